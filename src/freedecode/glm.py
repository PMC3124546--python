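"""FIR deconvolution of decision-locked responses.

Each decision is modeled with 20 finite-impulse-response regressors of one
TR (1.5 s) each, spanning a 30 s peristimulus window; the 10th bin is the
bin in which the decision was made, so bin b corresponds to lag
(b - 10) * TR seconds. Left- and right-choice trials form two separate
conditions; invalid trials (letter not recalled) get their own FIR set and
are excluded from decoding downstream. Probe button presses enter as two
canonical-HRF-convolved stick covariates (left and right hand separately),
plus a linear drift and a constant. Estimation is ordinary least squares
per voxel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .synth import BOLDRun, EventTable, canonical_hrf

__all__ = [
    "N_BINS",
    "DECISION_BIN",
    "DesignMatrix",
    "BetaMaps",
    "FIRGLM",
    "build_fir_design",
    "fit_fir_glm",
    "bin_to_lag",
]

N_BINS = 20
DECISION_BIN = 10  # 1-based: the bin in which the decision is made

CONDITIONS = ("left", "right")


def bin_to_lag(bin_1based: int | np.ndarray, tr: float = 1.5) -> float | np.ndarray:
    """Seconds relative to the decision for a 1-based FIR bin (negative = before)."""
    return (np.asarray(bin_1based) - DECISION_BIN) * tr


@dataclass
class DesignMatrix:
    """Scans x regressors matrix with labeled columns."""

    matrix: np.ndarray
    names: list[str]
    tr: float
    # 1-based bin -> column index, per condition
    fir_columns: dict[str, dict[int, int]]

    @property
    def n_scans(self) -> int:
        return self.matrix.shape[0]

    def column(self, name: str) -> np.ndarray:
        return self.matrix[:, self.names.index(name)]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.matrix, columns=self.names)


@dataclass
class BetaMaps:
    """Per-run FIR estimates over the in-mask voxels.

    ``beta`` has shape (n_conditions, N_BINS, n_mask_voxels) with the
    condition axis ordered ('left', 'right'); voxels follow C-order of the
    flattened mask. Invalid-trial and nuisance estimates are kept apart so
    decoding never sees them.
    """

    beta: np.ndarray
    conditions: tuple[str, ...]
    mask: np.ndarray
    resid_var: np.ndarray
    dof: int
    invalid_beta: np.ndarray | None = None
    nuisance: dict[str, np.ndarray] = field(default_factory=dict)
    run_id: int = 0

    def __post_init__(self) -> None:
        if self.beta.shape[1] != N_BINS:
            raise ValueError(f"bin axis must have length {N_BINS}")
        # a bin is either estimated everywhere on the mask or not at all
        # (NaN slabs mark bins whose indicators fell entirely outside the run)
        finite = np.isfinite(self.beta)
        slab_ok = finite.all(axis=2) | (~finite).all(axis=2)
        if not slab_ok.all():
            raise ValueError("estimates must be finite on the mask per modeled bin")

    @property
    def mask_index(self) -> np.ndarray:
        return np.flatnonzero(self.mask.ravel())

    def volume(self, condition: str, bin_1based: int) -> np.ndarray:
        """3D grid of estimates for one condition and bin; NaN outside the mask."""
        vol = np.full(self.mask.shape, np.nan)
        vol.ravel()[self.mask_index] = self.beta[self.conditions.index(condition), bin_1based - 1]
        return vol


def _scan_of(time_s: float, tr: float) -> int:
    # acquisition interval of scan k is [k*tr, (k+1)*tr)
    return int(np.floor(time_s / tr))


def build_fir_design(events: EventTable, n_scans: int, tr: float = 1.5) -> DesignMatrix:
    """Build the FIR + nuisance design for one run.

    For every trial and bin j in 1..20 a unit indicator is placed in the
    scan whose acquisition interval contains onset + (j - 10)*tr; bins
    falling outside the run are dropped (trials near the run boundary keep
    their in-run bins). Raises if either choice has no valid trial, or if
    the assembled design is rank deficient.
    """
    trials = events.trials
    valid = trials[trials["valid"]]
    for cond in CONDITIONS:
        if not (valid["choice"] == cond).any():
            raise ValueError(
                f"run {events.run_id}: no valid '{cond}' trials — decoding impossible"
            )
    if events.onsets.max() >= n_scans * tr:
        raise ValueError("events extend beyond the scan grid")

    blocks: list[np.ndarray] = []
    names: list[str] = []
    fir_columns: dict[str, dict[int, int]] = {}

    modeled = [("left", True), ("right", True)]
    if (~trials["valid"]).any():
        modeled.append(("invalid", False))

    for cond, needs_valid in modeled:
        if needs_valid:
            onsets = valid.loc[valid["choice"] == cond, "onset"].to_numpy(float)
        else:
            onsets = trials.loc[~trials["valid"], "onset"].to_numpy(float)
        block = np.zeros((n_scans, N_BINS))
        for onset in onsets:
            for j in range(1, N_BINS + 1):
                k = _scan_of(onset + (j - DECISION_BIN) * tr, tr)
                if 0 <= k < n_scans:
                    block[k, j - 1] = 1.0
        # bins that never land inside the run (boundary trials) are
        # unestimable; their columns are dropped and the estimates are NaN
        bins = [j for j in range(1, N_BINS + 1) if block[:, j - 1].any()]
        block = block[:, [j - 1 for j in bins]]
        fir_columns[cond] = {j: len(names) + i for i, j in enumerate(bins)}
        blocks.append(block)
        names.extend(f"{cond}_bin{j:02d}" for j in bins)

    # probe presses: HRF-convolved sticks, one regressor per hand
    scan_times = np.arange(n_scans) * tr
    for side in ("left", "right"):
        probe_onsets = trials.loc[trials["probe_side"] == side, "probe_onset"].to_numpy(float)
        reg = np.zeros(n_scans)
        for onset in probe_onsets:
            lags = scan_times - onset
            causal = lags >= 0
            reg[causal] += canonical_hrf(lags[causal])
        blocks.append(reg[:, None])
        names.append(f"probe_{side}")

    drift = np.linspace(-1.0, 1.0, n_scans)
    blocks.append(drift[:, None])
    names.append("drift")
    blocks.append(np.ones((n_scans, 1)))
    names.append("constant")

    X = np.hstack(blocks)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        collinear = _collinear_columns(X, names)
        raise ValueError(
            f"design matrix is rank deficient (rank {rank} < {X.shape[1]}); "
            f"collinear columns: {collinear}"
        )
    return DesignMatrix(matrix=X, names=names, tr=tr, fir_columns=fir_columns)


def _collinear_columns(X: np.ndarray, names: list[str]) -> list[str]:
    _, R = np.linalg.qr(X)
    small = np.abs(np.diag(R)) < 1e-10 * max(1.0, np.abs(np.diag(R)).max())
    return [names[i] for i in np.flatnonzero(small)]


def fit_fir_glm(run: BOLDRun, design: DesignMatrix) -> BetaMaps:
    """Ordinary-least-squares fit of the FIR design to one run's voxels."""
    if design.n_scans != run.n_scans:
        raise ValueError(
            f"design has {design.n_scans} rows but run has {run.n_scans} scans"
        )
    mask_idx = np.flatnonzero(run.mask.ravel())
    if mask_idx.size == 0:
        raise ValueError("mask is empty")
    Y = run.data.reshape(-1, run.n_scans)[mask_idx].T.astype(np.float64)
    bad = ~np.all(np.isfinite(Y), axis=0)
    if bad.any():
        raise ValueError(
            f"non-finite data in {int(bad.sum())} mask voxels "
            f"(first flat indices: {mask_idx[bad][:10].tolist()})"
        )
    X = design.matrix
    coef, _, rank, _ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ coef
    dof = int(X.shape[0] - rank)
    resid_var = (resid**2).sum(axis=0) / max(dof, 1)

    def fir_block(cond: str) -> np.ndarray:
        cols = design.fir_columns[cond]
        out = np.full((N_BINS, Y.shape[1]), np.nan)
        for j, c in cols.items():
            out[j - 1] = coef[c]
        return out

    beta = np.stack([fir_block(c) for c in CONDITIONS])
    invalid = fir_block("invalid") if "invalid" in design.fir_columns else None
    nuisance = {
        name: coef[design.names.index(name)]
        for name in ("probe_left", "probe_right", "drift", "constant")
    }
    return BetaMaps(
        beta=beta,
        conditions=CONDITIONS,
        mask=run.mask,
        resid_var=resid_var,
        dof=dof,
        invalid_beta=invalid,
        nuisance=nuisance,
        run_id=run.run_id,
    )


class FIRGLM:
    """Estimator interface around the FIR design + OLS fit.

    Parameters
    ----------
    tr : repetition time in seconds.

    Attributes (after ``fit``)
    --------------------------
    designs_ : list of DesignMatrix, one per run.
    betas_ : list of BetaMaps, one per run.
    """

    def __init__(self, tr: float = 1.5):
        self.tr = tr

    def get_params(self, deep: bool = True) -> dict:
        return {"tr": self.tr}

    def set_params(self, **params) -> "FIRGLM":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, runs: list[BOLDRun], events: list[EventTable]) -> "FIRGLM":
        if len(runs) != len(events):
            raise ValueError("need one event table per run")
        self.designs_ = [
            build_fir_design(table, n_scans=run.n_scans, tr=self.tr)
            for run, table in zip(runs, events)
        ]
        self.betas_ = [
            fit_fir_glm(run, design) for run, design in zip(runs, self.designs_)
        ]
        return self
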