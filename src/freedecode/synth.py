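"""Synthetic behavior and BOLD generator for self-paced binary-decision experiments.

The generator emulates the statistical structure the downstream analyses
assume: subjects press a left or right button at their own pace (one
decision every ~15-50 s), each decision is followed by a probe press a
few seconds later, and the volume time series contains

* a choice-independent univariate response over the whole brain mask that
  rises only *after* each decision (canonical-HRF shaped),
* a choice-*dependent* fine-grained multivoxel pattern confined to a small
  "informative" region whose amplitude ramps up linearly toward the moment
  of the decision and vanishes (or drops to a configurable level)
  afterwards, and
* AR(1) + white noise plus a linear scanner drift.

The two choice templates are zero-mean over the informative region, so the
regional *mean* signal carries no choice information: the pattern is
visible to a multivariate decoder but invisible to univariate contrasts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "BehaviorConfig",
    "EventTable",
    "VolumeLayout",
    "SignalConfig",
    "PatternTemplates",
    "BOLDRun",
    "simulate_behavior",
    "canonical_hrf",
    "make_pattern_templates",
    "simulate_subject_bold",
    "truncated_exponential_rate",
]

EVENT_COLUMNS = ["onset", "choice", "valid", "probe_onset", "probe_side", "letter_offset"]


@dataclass(frozen=True)
class BehaviorConfig:
    """Parameters of the self-paced decision task.

    Defaults mirror the study design: 10 runs of 5 minutes sampled at
    TR = 1.5 s, decisions arriving every 15-50 s with a mean gap of
    29.7 s, balanced left/right choices, ~1% invalid trials, and a probe
    screen presented 1-2.5 s after the decision.
    """

    n_runs: int = 10
    run_duration: float = 300.0
    tr: float = 1.5
    mean_iti: float = 29.7
    iti_bounds: tuple[float, float] = (15.0, 50.0)
    p_left: float = 0.5
    p_invalid: float = 0.01
    probe_delay_choices: tuple[float, ...] = (1.0, 1.5, 2.0, 2.5)
    p_letter_lag: float = 0.15  # probability the reported letter is the one before the press
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.iti_bounds
        if not (0 <= self.p_left <= 1):
            raise ValueError(f"p_left must lie in [0, 1], got {self.p_left}")
        if not (lo < self.mean_iti < hi):
            raise ValueError(
                f"mean_iti must lie strictly inside iti_bounds, got {self.mean_iti} "
                f"outside ({lo}, {hi})"
            )
        if self.mean_iti >= (lo + hi) / 2:
            raise ValueError(
                "mean_iti must be below the iti_bounds midpoint for a truncated "
                f"exponential: {self.mean_iti} >= {(lo + hi) / 2}"
            )
        if self.run_duration / self.mean_iti < 2:
            raise ValueError("run too short: run_duration / mean_iti must be >= 2")
        if not (0 <= self.p_invalid < 1):
            raise ValueError("p_invalid must lie in [0, 1)")
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")


@dataclass
class EventTable:
    """Per-run trial list.

    ``trials`` columns: onset (decision time, s), choice ('left'/'right'),
    valid (bool), probe_onset (s), probe_side, letter_offset (0 or -1).
    """

    run_id: int
    trials: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in EVENT_COLUMNS if c not in self.trials.columns]
        if missing:
            raise ValueError(f"EventTable missing columns: {missing}")
        onsets = self.trials["onset"].to_numpy(float)
        if onsets.size and not np.all(np.diff(onsets) > 0):
            raise ValueError("decision onsets must be strictly increasing")

    @property
    def onsets(self) -> np.ndarray:
        return self.trials["onset"].to_numpy(float)

    @property
    def choices(self) -> np.ndarray:
        return self.trials["choice"].to_numpy(str)

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    def __eq__(self, other: object) -> bool:
        # equality at the serialized (6-decimal) precision of the TSV format
        if not isinstance(other, EventTable):
            return NotImplemented
        if self.run_id != other.run_id or len(self.trials) != len(other.trials):
            return False
        a = self.trials.reset_index(drop=True)
        b = other.trials.reset_index(drop=True)
        for col in EVENT_COLUMNS:
            if col in ("onset", "probe_onset"):
                if not np.allclose(a[col].to_numpy(float), b[col].to_numpy(float), atol=5e-7):
                    return False
            elif not (a[col].to_numpy() == b[col].to_numpy()).all():
                return False
        return True


@dataclass(frozen=True)
class VolumeLayout:
    """Spatial layout of the simulated volume.

    A cubic grid of 1 mm isotropic voxels with a spherical brain mask and
    a smaller spherical informative region at the grid center, standing in
    for the imaged frontopolar slab.
    """

    shape: tuple[int, int, int] = (24, 24, 24)
    voxel_size_mm: float = 1.0
    mask_radius: float = 10.0
    region_radius: float = 4.0

    @property
    def mask(self) -> np.ndarray:
        return self._sphere(self.mask_radius)

    @property
    def informative_region(self) -> np.ndarray:
        region = self._sphere(self.region_radius)
        return region & self.mask

    def _sphere(self, radius: float) -> np.ndarray:
        center = (np.array(self.shape) - 1) / 2.0
        grids = np.indices(self.shape)
        d2 = sum((g - c) ** 2 for g, c in zip(grids, center))
        return d2 <= radius**2

    def validate(self) -> None:
        if not self.mask.any():
            raise ValueError("brain mask is empty")
        if not (self.informative_region & self.mask).sum() == self.informative_region.sum():
            raise ValueError("informative region must be contained in the mask")


@dataclass(frozen=True)
class SignalConfig:
    """Amplitudes and noise of the simulated BOLD signal.

    ``pattern_amplitude`` is the peak (at-decision) amplitude of the
    choice-specific pattern envelope; the envelope rises linearly from 0
    starting ``ramp_onset`` seconds before each decision and takes the
    value ``post_decision_pattern`` afterwards. ``univariate_amplitude``
    scales a choice-independent canonical-HRF response time-locked to the
    decision (peaking ~5 s after it). Noise is stationary AR(1) with
    marginal standard deviation ``noise_sd`` plus a linear drift.
    """

    pattern_amplitude: float = 2.0
    ramp_onset: float = 9.0
    post_decision_pattern: float = 0.0
    univariate_amplitude: float = 3.0
    noise_sd: float = 1.0
    temporal_ar1: float = 0.3
    drift: float = 0.005
    baseline: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ramp_onset <= 0:
            raise ValueError("ramp_onset must be > 0")
        if not (0 <= self.temporal_ar1 < 1):
            raise ValueError("temporal_ar1 must lie in [0, 1)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")


@dataclass(frozen=True)
class PatternTemplates:
    """Two zero-mean, unit-norm, mutually orthogonal weight maps over the
    informative region — the spatial 'fingerprints' of the two choices."""

    left: np.ndarray
    right: np.ndarray


@dataclass
class BOLDRun:
    """One run's 4D intensity grid (x, y, z, t) with its TR and mask."""

    run_id: int
    data: np.ndarray
    tr: float
    mask: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        if self.data.ndim != 4:
            raise ValueError(f"BOLD data must be 4D, got {self.data.ndim}D")
        if self.mask.shape != self.data.shape[:3]:
            raise ValueError("mask grid does not match BOLD spatial grid")

    @property
    def n_scans(self) -> int:
        return self.data.shape[3]


def truncated_exponential_rate(mean: float, bounds: tuple[float, float]) -> float:
    """Rate of an exponential truncated to ``bounds`` with the given mean.

    The truncated mean is a + 1/lam - (b-a)/(exp(lam*(b-a)) - 1); it runs
    from (a+b)/2 (lam -> 0) down to a (lam -> inf), so the target mean must
    lie strictly between a and the interval midpoint.
    """
    a, b = bounds
    w = b - a

    def trunc_mean(lam: float) -> float:
        return a + 1.0 / lam - w / np.expm1(lam * w)

    if not (a < mean < (a + b) / 2):
        raise ValueError(f"target mean {mean} not attainable on [{a}, {b}]")
    return optimize.brentq(lambda lam: trunc_mean(lam) - mean, 1e-8, 10.0 / w * 50)


def _sample_truncated_exponential(
    rng: np.random.Generator, n: int, rate: float, bounds: tuple[float, float]
) -> np.ndarray:
    a, b = bounds
    u = rng.random(n)
    # inverse CDF of exp(rate) conditioned on [a, b]
    return a - np.log1p(-u * (-np.expm1(-rate * (b - a)))) / rate


def simulate_behavior(cfg: BehaviorConfig) -> list[EventTable]:
    """Draw one event table per run.

    Inter-decision gaps are truncated-exponential with the configured mean
    (memoryless within the allowed pace window); choices are i.i.d.
    Bernoulli(p_left). Deterministic for a fixed ``cfg.seed``.
    """
    rate = truncated_exponential_rate(cfg.mean_iti, cfg.iti_bounds)
    root = np.random.SeedSequence(cfg.seed)
    tables = []
    for run_id, child in enumerate(root.spawn(cfg.n_runs)):
        rng = np.random.default_rng(child)
        onsets: list[float] = []
        t = 0.0
        margin = max(cfg.probe_delay_choices)
        while True:
            gap = float(_sample_truncated_exponential(rng, 1, rate, cfg.iti_bounds)[0])
            t += gap
            if t + margin >= cfg.run_duration:
                break
            onsets.append(t)
        if len(onsets) < 2:
            raise ValueError(
                f"run {run_id} too short for at least 2 trials "
                f"(duration {cfg.run_duration}s, mean gap {cfg.mean_iti}s)"
            )
        n = len(onsets)
        choices = np.where(rng.random(n) < cfg.p_left, "left", "right")
        valid = rng.random(n) >= cfg.p_invalid
        probe_delay = rng.choice(np.asarray(cfg.probe_delay_choices, float), size=n)
        probe_side = np.where(rng.random(n) < 0.5, "left", "right")
        letter_offset = np.where(rng.random(n) < cfg.p_letter_lag, -1, 0)
        # microsecond precision so the 6-decimal TSV round-trips losslessly
        onsets = np.round(np.asarray(onsets, float), 6)
        probe_delay = np.round(probe_delay, 6)
        trials = pd.DataFrame(
            {
                "onset": onsets,
                "choice": choices,
                "valid": valid,
                "probe_onset": np.asarray(onsets) + probe_delay,
                "probe_side": probe_side,
                "letter_offset": letter_offset.astype(int),
            }
        )
        tables.append(EventTable(run_id=run_id, trials=trials))
    return tables


# Double-gamma shape constants (SPM convention): response gamma peaking at
# 5 s, undershoot gamma peaking at 15 s, undershoot 1/6 of the peak.
_HRF_RESPONSE_SHAPE = 6.0
_HRF_UNDERSHOOT_SHAPE = 16.0
_HRF_UNDERSHOOT_RATIO = 1.0 / 6.0


def canonical_hrf(time_points: np.ndarray | Sequence[float]) -> np.ndarray:
    """Canonical double-gamma haemodynamic response, unit peak amplitude.

    Peak near 5 s, undershoot near 15 s with 1:6 amplitude ratio;
    effectively zero beyond ~32 s. Raises on negative times (the response
    is causal).
    """
    t = np.asarray(time_points, dtype=float)
    if np.any(t < 0):
        raise ValueError("HRF is causal: time points must be >= 0")
    raw = stats.gamma.pdf(t, _HRF_RESPONSE_SHAPE) - _HRF_UNDERSHOOT_RATIO * stats.gamma.pdf(
        t, _HRF_UNDERSHOOT_SHAPE
    )
    return raw / _HRF_PEAK


def _hrf_peak() -> float:
    dense = np.linspace(0.0, 30.0, 3001)
    raw = stats.gamma.pdf(dense, _HRF_RESPONSE_SHAPE) - _HRF_UNDERSHOOT_RATIO * stats.gamma.pdf(
        dense, _HRF_UNDERSHOOT_SHAPE
    )
    return float(raw.max())


_HRF_PEAK = _hrf_peak()


def make_pattern_templates(region_size: int, seed: int) -> PatternTemplates:
    """Draw two zero-mean, unit-norm, mutually orthogonal weight vectors.

    Orthogonality plus zero mean needs at least 3 voxels (the zero-mean
    subspace of R^n has dimension n-1).
    """
    if region_size < 3:
        raise ValueError(
            f"informative region must have >= 3 voxels for two orthogonal "
            f"zero-mean templates, got {region_size}"
        )
    rng = np.random.default_rng(seed)
    a = rng.standard_normal(region_size)
    b = rng.standard_normal(region_size)
    a -= a.mean()
    a /= np.linalg.norm(a)
    b -= b.mean()
    b -= (b @ a) * a
    norm_b = np.linalg.norm(b)
    if norm_b < 1e-12:  # measure-zero under continuous draws
        raise RuntimeError("degenerate template draw; use a different seed")
    b /= norm_b
    return PatternTemplates(left=a, right=b)


def _pattern_envelope(lags: np.ndarray, sig: SignalConfig) -> np.ndarray:
    """Choice-pattern amplitude as a function of lag (s) relative to the decision.

    0 before the ramp starts, linear rise to ``pattern_amplitude`` at lag 0,
    ``post_decision_pattern`` for positive lags. This is the realized
    signal-level time course: information is present only before the
    decision, which is the empirical structure the pipeline must recover.
    """
    env = np.zeros_like(lags, dtype=float)
    ramp = (lags >= -sig.ramp_onset) & (lags <= 0)
    env[ramp] = sig.pattern_amplitude * (1.0 + lags[ramp] / sig.ramp_onset)
    env[lags > 0] = sig.post_decision_pattern
    return env


def simulate_subject_bold(
    events: Sequence[EventTable],
    layout: VolumeLayout,
    sig: SignalConfig,
    templates: PatternTemplates | None = None,
    tr: float = 1.5,
    run_duration: float = 300.0,
) -> list[BOLDRun]:
    """Simulate one subject's 4D runs from event tables.

    Each voxel time course is baseline + linear drift + AR(1) noise,
    plus (whole mask) a choice-independent HRF response after each
    decision, plus (informative region only) the chosen side's template
    scaled by the pre-decision ramp envelope. Bit-reproducible for fixed
    seeds. Volumes are sampled instantaneously at multiples of TR.
    """
    layout.validate()
    region_idx = np.flatnonzero(layout.informative_region.ravel())
    if sig.pattern_amplitude != 0 and region_idx.size == 0:
        raise ValueError("informative region is empty but pattern_amplitude > 0")
    if templates is None and region_idx.size >= 3:
        templates = make_pattern_templates(region_idx.size, seed=sig.seed)
    mask_flat = layout.mask.ravel()
    for table in events:
        if table.onsets.max() >= run_duration:
            raise ValueError(f"run {table.run_id} has events beyond run_duration")

    root = np.random.SeedSequence((sig.seed, 0x0B01D))
    children = root.spawn(len(events))
    return [
        _simulate_run(
            table,
            layout,
            sig,
            templates,
            np.random.default_rng(child),
            mask_flat,
            region_idx,
            tr=tr,
            run_duration=run_duration,
        )
        for table, child in zip(events, children)
    ]


def _simulate_run(
    table: EventTable,
    layout: VolumeLayout,
    sig: SignalConfig,
    templates: PatternTemplates | None,
    rng: np.random.Generator,
    mask_flat: np.ndarray,
    region_idx: np.ndarray,
    tr: float = 1.5,
    run_duration: float = 300.0,
) -> BOLDRun:
    n_scans = int(round(run_duration / tr))
    scan_times = np.arange(n_scans) * tr
    n_vox = mask_flat.size
    n_mask = int(mask_flat.sum())

    # choice-independent post-decision response, shared across the mask
    univar = np.zeros(n_scans)
    for onset in table.onsets:
        lags = scan_times - onset
        future = lags >= 0
        univar[future] += sig.univariate_amplitude * canonical_hrf(lags[future])

    # choice-specific envelopes
    env_left = np.zeros(n_scans)
    env_right = np.zeros(n_scans)
    for onset, choice in zip(table.onsets, table.choices):
        env = _pattern_envelope(scan_times - onset, sig)
        if choice == "left":
            env_left += env
        else:
            env_right += env

    data = np.zeros((n_vox, n_scans), dtype=np.float64)
    in_mask = np.flatnonzero(mask_flat)
    # stationary AR(1) noise, marginal sd = noise_sd
    rho = sig.temporal_ar1
    innov_sd = sig.noise_sd * np.sqrt(1.0 - rho**2)
    noise = np.empty((n_mask, n_scans))
    noise[:, 0] = rng.standard_normal(n_mask) * sig.noise_sd
    eps = rng.standard_normal((n_mask, n_scans - 1)) * innov_sd
    for t in range(1, n_scans):
        noise[:, t] = rho * noise[:, t - 1] + eps[:, t - 1]

    data[in_mask] = sig.baseline + sig.drift * scan_times + univar + noise
    if templates is not None and (sig.pattern_amplitude != 0 or sig.post_decision_pattern != 0):
        data[region_idx] += np.outer(templates.left, env_left) + np.outer(
            templates.right, env_right
        )

    grid = data.reshape(layout.shape + (n_scans,)).astype(np.float32)
    return BOLDRun(run_id=table.run_id, data=grid, tr=tr, mask=layout.mask.copy())
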