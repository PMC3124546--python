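# Methods

`freedecode` implements a time-resolved multivariate decoding analysis of
self-paced binary motor decisions, together with the synthetic-data
generator used to validate every stage. This note documents the models,
the parameters that matter, and the design choices made where the design
was genuinely open.

## The analysis

**Task structure.** A subject freely presses a left or right button every
15–50 s (mean gap ≈ 29.7 s) across ten 5-minute runs sampled at
TR = 1.5 s. Each decision is followed ~1–2.5 s later by a probe press
reporting which letter of a continuously refreshed stream was on screen
when the decision became conscious. Rare trials where no letter can be
recalled are *invalid*.

**FIR deconvolution.** Left- and right-choice trials are modeled as two
conditions with 20 finite-impulse-response regressors of one TR each,
tiling a 30 s peristimulus window; bin 10 is the bin containing the
decision, so bin *b* sits at lag (b − 10)·1.5 s. Invalid trials receive
their own 20-bin FIR set and are excluded from decoding. Probe presses
enter as two canonical-HRF-convolved stick covariates (left and right
hand separately), plus a linear drift and a constant per run. Estimation
is ordinary least squares per voxel. The FIR indicator for bin *b* of a
trial at onset *t* is placed in the scan whose acquisition interval
[k·TR, (k+1)·TR) contains t + (b − 10)·TR; bins falling outside the run
are dropped, keeping the trial's remaining bins. We deliberately do not
prewhiten: residual autocorrelation biases single-run standard errors,
not the group inference, which operates across subjects.

**Searchlight decoding.** For every voxel, the sphere of all voxels
within a 3-voxel radius (123 voxels when fully in-mask) defines one
pattern per condition per run at each bin. A linear soft-margin SVM with
fixed C = 1 is trained on the patterns of all runs but one (one exemplar
per condition per run) and tested on the held-out run's two patterns;
cycling the held-out run gives 10-fold leave-one-run-out accuracy, which
is assigned to the center voxel. Ties on the decision boundary go to the
canonical first class ("left") — a measure-zero event under continuous
noise. Centers whose sphere keeps less than half its voxels inside the
mask are not scored (NaN). Pattern vectors are used raw (no per-sphere
centering or scaling); a scaling step can be added upstream but is off by
default since the choice is analytically open.

**Group inference.** Per bin, subject accuracy maps are smoothed with a
3 mm FWHM Gaussian (NaN-aware normalized convolution so invalid centers
neither receive nor contribute weight), restricted to voxels shared by
all subjects, and tested per voxel against chance (50%) with a one-sided
one-sample t-test. Benjamini–Hochberg FDR at q = .05 is applied per
time-bin over in-mask voxels; surviving voxels are grouped by
26-connectivity and clusters below 5 voxels discarded. The univariate
control contrasts left vs right estimates per voxel with a two-sided
paired t-test at the liberal uncorrected p < .001 — by construction of
the generator it should (and does) find nothing.

**Temporal pattern stability.** At the single center maximizing the
*group-mean* accuracy at the bin directly preceding the decision (bin 9,
−1.5 s; deliberately not re-selected per subject), patterns from k = 2,
3, 4 adjacent bins are combined by element-wise averaging (length N) or
concatenation (length k·N), in windows tiling backward from bin 10, and
the decoder is rerun on the combined vectors. Pattern persistence is
additionally measured as the Pearson correlation of each bin's vector
with the preceding bin's, per condition and run, then averaged.

**Behavioral statistics.** Choice balance is a df = 1 goodness-of-fit
chi-square against 50/50. Same-choice sequence lengths are tallied into a
percentage histogram (run boundaries break sequences; configurable) and
fitted with f(x) = 100·c·e^(−c·x) by least squares; i.i.d. fair choices
give geometric run lengths, i.e. c near ln 2 ≈ 0.693. Each run's choice
sequence gets a Wald–Wolfowitz runs test (normal approximation with
continuity correction; Bonferroni across a subject's runs; runs with a
single choice are reported as skipped). Consecutive runs' sequences,
coded ±1 and truncated to the shorter run, are Pearson-correlated.
Screening excludes subjects whose choice ratio *exceeds* 2:1 (exactly 2:1
passes) or whose mean inter-decision interval falls outside 15–50 s.

## The synthetic generator

The generator emulates the statistical structure the analysis assumes,
not any particular dataset:

* **Events.** Inter-decision gaps are truncated-exponential on [15, 50] s
  with the rate solved so the truncated mean equals 29.7 s (memoryless
  pacing is the simplest process consistent with the near-exponential
  sequence behavior); choices are i.i.d. Bernoulli(0.5); ~1% of trials
  are invalid; probe delays are drawn from {1, 1.5, 2, 2.5} s.
* **Volume.** A 24³ grid of 1 mm voxels with a spherical brain mask
  (radius 10) and a spherical informative region (radius 4, 257 voxels)
  at the center, standing in for the imaged prefrontal slab. Tests and
  the acceptance script use smaller grids (10³–16³) purely to keep
  simulated problem sizes desk-scale; nothing in the method depends on
  grid size.
* **Choice patterns.** Two zero-mean, unit-norm, mutually orthogonal
  weight maps over the region, one per choice. Zero mean makes the
  regional average identical for both choices at every lag — the signal
  is visible to a pattern classifier and invisible to univariate
  contrasts, which is the phenomenon of interest.
* **Temporal envelope.** The pattern amplitude rises linearly from 0
  starting 9 s before each decision (decodability from roughly −7.5 s
  plus hemodynamic delay motivates the onset) to `pattern_amplitude` at
  the decision, and equals `post_decision_pattern` (default 0)
  afterwards. The envelope is specified at signal level: the latent
  neural time course is unknown, and specifying the realized BOLD-level
  envelope is the only way to make information vanish after the decision
  exactly, as observed empirically. Convolving a neural ramp with an HRF
  would instead smear choice information several seconds past the
  decision.
* **Univariate response.** A choice-independent canonical-HRF response
  (double gamma, response peak ~5 s, undershoot ~15 s at 1:6 ratio,
  unit peak) time-locked to each decision, identical across the mask:
  the average signal rises only *after* the decision.
* **Noise.** Stationary AR(1) per voxel (lag-1 coefficient 0.3, marginal
  SD `noise_sd`) plus a linear drift and a constant baseline of 100 —
  the minimal model producing realistic temporal autocorrelation.
* **Seeding.** All randomness flows from one master seed through
  numpy `SeedSequence` spawning, one stream per run and per subject;
  identical seeds give bit-identical volumes.

**Amplitude calibration.** No SNR is available to target, so the default
`pattern_amplitude = 2.0` (with `noise_sd = 1.0`) was chosen once so that
single-subject decoding at the region center peaks around 85–95% just
before the decision — strong enough that six synthetic subjects recover
the planted region at group level, while pre-ramp and post-decision bins
stay at chance. `univariate_amplitude = 3.0` gives a clearly visible
post-decision percent-signal deflection. These are calibration knobs of
the generator, not claims about any empirical effect size; group-level
accuracies reported by the pipeline on synthetic data are therefore
higher than what small real-data effects would produce.

**What the generator does not emulate.** Head motion, slice-timing and
multiband effects, spatial noise correlations, susceptibility dropout,
between-subject anatomical variability (synthetic subjects share one
space, so normalization is a no-op), letter-stream rendering, and
timing-judgment error. Passing tests therefore demonstrate correctness
of the estimation and inference machinery under the stated generative
model, not robustness to those nuisances.

## Numerical choices and degenerate inputs

* One exemplar per (condition, run): 18 training vectors in ≥100
  dimensions. The SVM fit is deterministic; libsvm's dual solver is used
  via scikit-learn, and fold predictions are taken from the sign of the
  decision function.
* Sphere offsets are ordered lexicographically by (dx, dy, dz), fixing
  the feature layout across runs and subjects.
* A run in which either choice has no valid trial, or whose design is
  rank deficient (e.g. a lone trial of one condition sharing every scan
  with a lone invalid trial), raises an error naming the columns; batch
  drivers treat such subjects as excluded, the synthetic analogue of
  behavioral screening.
* FIR bins whose indicators fall entirely outside the run (boundary
  trials of a condition with a single trial) are dropped from the design
  and reported as NaN slabs; decoding at such bins raises rather than
  silently imputing.
* Group-test voxels with zero between-subject variance get p = 0 if the
  mean beats chance and p = 1 otherwise, with a log entry.
* Smoothing uses σ = FWHM / (2√(2 ln 2)) in voxel units.
* Windows for bin combination tile backward from bin 10 (and forward
  from bin 11 when post-decision bins are supplied); leftover earliest
  bins are dropped.
* The truncated-exponential rate is solved by Brent's method; the target
  mean must lie strictly between the lower bound and the interval
  midpoint, the attainable range of a truncated exponential.

## Known limitations

* With one exemplar per class per run, per-subject null accuracy has
  high variance (SD ≈ 0.05–0.07 over a small mask) and a run-count-
  dependent wobble; it is unbiased across seeds (50.4% ± 1.3% over 30
  designs). Null-calibration checks therefore average over seeds.
* The runs-test normal approximation deviates from the exact permutation
  null by up to ~0.16 near the distribution center for strongly
  unbalanced short sequences, while remaining conservative (and within
  0.04) in the p ≤ .05 tail that decisions rest on.
* FDR is controlled per time-bin, not jointly across bins; a pooled mode
  is available (`fdr_cluster_threshold` on concatenated grids) but
  per-bin is the default, matching the per-time-point group analyses.
* Probe covariates are time-locked to the probe press, not the response
  screen onset; the two are 0–2.5 s apart and the choice is flagged, not
  asserted.
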