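"""Spherical-searchlight decoding of choice from FIR estimates.

For every voxel, the FIR estimates of the surrounding sphere (radius 3
voxels by default) form one pattern vector per condition per run at each
peristimulus time-bin. A linear support-vector machine with fixed C = 1 is
trained on the vectors of all runs but one and tested on the held-out
run's two vectors; cycling the held-out run gives leave-one-run-out
cross-validated accuracy, which is assigned to the sphere's center voxel.
Repeating over all centers and all 20 bins yields a time-resolved 3D
accuracy map.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.svm import SVC

from .glm import N_BINS, BetaMaps

__all__ = [
    "SearchlightSpec",
    "PatternVectors",
    "sphere_offsets",
    "extract_patterns",
    "loro_decode",
    "accuracy_map",
    "SearchlightDecoder",
]

logger = logging.getLogger(__name__)

LABELS = ("left", "right")  # canonical class order; ties resolve to 'left'


@dataclass(frozen=True)
class SearchlightSpec:
    """Searchlight geometry and classifier settings."""

    radius: float = 3.0
    C: float = 1.0
    min_in_mask_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.radius < 1:
            raise ValueError("radius must be >= 1 voxel")
        if self.C <= 0:
            raise ValueError("C must be positive")


@dataclass
class PatternVectors:
    """Pattern vectors for one searchlight sphere at one time-bin.

    ``X`` has one row per (condition, run) sample — shape
    (2 * n_runs, n_sphere_voxels) — with labels ``y`` (0 = left,
    1 = right) and run indices ``runs``. Voxel order is identical across
    rows (lexicographic sphere offsets restricted to the mask).
    """

    X: np.ndarray
    y: np.ndarray
    runs: np.ndarray

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.X)):
            raise ValueError("pattern vectors contain non-finite values")
        if len(self.X) != len(self.y) or len(self.y) != len(self.runs):
            raise ValueError("inconsistent sample count")

    @property
    def n_runs(self) -> int:
        return int(np.unique(self.runs).size)

    @property
    def n_features(self) -> int:
        return self.X.shape[1]


def sphere_offsets(radius: float) -> np.ndarray:
    """All integer (dx, dy, dz) with dx^2+dy^2+dz^2 <= radius^2.

    Lexicographic order; includes the origin. Radius 3 gives 123 offsets.
    """
    if radius < 1:
        raise ValueError("radius must be >= 1 voxel")
    r = int(np.floor(radius))
    axis = np.arange(-r, r + 1)
    dx, dy, dz = np.meshgrid(axis, axis, axis, indexing="ij")
    offs = np.stack([dx.ravel(), dy.ravel(), dz.ravel()], axis=1)
    keep = (offs**2).sum(axis=1) <= radius**2
    return offs[keep]  # meshgrid 'ij' + ravel is already lexicographic


class _InvalidCenter(Exception):
    """Sphere has too few in-mask voxels to form a pattern."""


def _sphere_columns(
    center: tuple[int, int, int],
    offsets: np.ndarray,
    mask: np.ndarray,
    col_of_voxel: np.ndarray,
    min_fraction: float,
) -> np.ndarray:
    coords = offsets + np.asarray(center)
    in_bounds = np.all((coords >= 0) & (coords < mask.shape), axis=1)
    coords = coords[in_bounds]
    flat = np.ravel_multi_index(coords.T, mask.shape)
    cols = col_of_voxel[flat]
    cols = cols[cols >= 0]
    if cols.size < min_fraction * len(offsets):
        raise _InvalidCenter(center)
    return cols


def _column_lookup(mask: np.ndarray) -> np.ndarray:
    """Flat voxel index -> position in the mask-voxel axis of BetaMaps (-1 outside)."""
    lut = np.full(mask.size, -1, dtype=np.int64)
    lut[np.flatnonzero(mask.ravel())] = np.arange(int(mask.sum()))
    return lut


def extract_patterns(
    betas: list[BetaMaps],
    center: tuple[int, int, int],
    spec: SearchlightSpec,
    bin_1based: int,
) -> PatternVectors:
    """Pattern vectors of the sphere at ``center`` for one time-bin.

    One vector per (condition, run); invalid-trial estimates never enter.
    Raises ``ValueError`` if the center's in-mask sphere fraction is below
    the spec minimum.
    """
    if not 1 <= bin_1based <= N_BINS:
        raise ValueError(f"bin must be in 1..{N_BINS}")
    mask = betas[0].mask
    if not mask[center]:
        raise ValueError(f"center {center} is outside the mask")
    offsets = sphere_offsets(spec.radius)
    lut = _column_lookup(mask)
    try:
        cols = _sphere_columns(center, offsets, mask, lut, spec.min_in_mask_fraction)
    except _InvalidCenter:
        raise ValueError(
            f"center {center}: in-mask sphere fraction below "
            f"{spec.min_in_mask_fraction}"
        ) from None
    return _patterns_at(betas, cols, bin_1based)


def _patterns_at(betas: list[BetaMaps], cols: np.ndarray, bin_1based: int) -> PatternVectors:
    rows, labels, runs = [], [], []
    for r, bm in enumerate(betas):
        for li, cond in enumerate(LABELS):
            rows.append(bm.beta[bm.conditions.index(cond), bin_1based - 1, cols])
            labels.append(li)
            runs.append(r)
    return PatternVectors(
        X=np.asarray(rows), y=np.asarray(labels), runs=np.asarray(runs)
    )


def _fold_predict(X_train, y_train, X_test, C: float) -> np.ndarray:
    """Linear max-margin fold; decision-boundary ties resolve to class 0 (left)."""
    clf = SVC(kernel="linear", C=C)
    clf.fit(X_train, y_train)
    d = clf.decision_function(X_test)
    return (d > 0).astype(int)  # classes_ sorted -> positive side is class 1


def loro_folds(run_ids: np.ndarray) -> list[tuple[np.ndarray, np.ndarray]]:
    """Leave-one-run-out folds: one (train_runs, test_run) pair per run."""
    unique = np.unique(run_ids)
    return [(unique[unique != held], np.array([held])) for held in unique]


def loro_decode(patterns: PatternVectors, spec: SearchlightSpec) -> float:
    """Leave-one-run-out cross-validated accuracy (fraction correct).

    Each run is held out once; the classifier is refit on the remaining
    runs' (condition, run) vectors. Degenerate spheres with identical
    constant patterns across classes score 0.5 by convention.
    """
    if np.unique(patterns.runs).size < 3:
        raise ValueError("leave-one-run-out needs at least 3 runs")
    X, y, runs = patterns.X, patterns.y, patterns.runs
    if np.ptp(X) == 0.0:
        logger.debug("degenerate constant patterns; accuracy 0.5 by convention")
        return 0.5
    correct = 0
    total = 0
    for _, (held,) in loro_folds(runs):
        test = runs == held
        train = ~test
        if np.unique(y[train]).size < 2:
            raise ValueError("both classes must be present in every training fold")
        pred = _fold_predict(X[train], y[train], X[test], spec.C)
        correct += int((pred == y[test]).sum())
        total += int(test.sum())
    return correct / total


def accuracy_map(
    betas: list[BetaMaps],
    mask: np.ndarray | None = None,
    spec: SearchlightSpec = SearchlightSpec(),
    bin_1based: int = 9,
) -> np.ndarray:
    """3D decoding-accuracy grid at one time-bin; NaN at invalid centers."""
    if mask is None:
        mask = betas[0].mask
    if not mask.any():
        raise ValueError("mask is empty")
    offsets = sphere_offsets(spec.radius)
    lut = _column_lookup(betas[0].mask)
    out = np.full(mask.shape, np.nan)
    centers = np.argwhere(mask)
    # gather all (condition, run, voxel) betas for this bin once
    stack = np.stack(
        [bm.beta[:, bin_1based - 1, :] for bm in betas]
    )  # (n_runs, 2, n_maskvox)
    n_runs = len(betas)
    y = np.tile([0, 1], n_runs)
    runs = np.repeat(np.arange(n_runs), 2)
    for center in map(tuple, centers):
        try:
            cols = _sphere_columns(center, offsets, betas[0].mask, lut, spec.min_in_mask_fraction)
        except _InvalidCenter:
            continue
        X = stack[:, :, cols].reshape(2 * n_runs, -1)
        pv = PatternVectors(X=X, y=y, runs=runs)
        out[center] = loro_decode(pv, spec)
    return out


class SearchlightDecoder:
    """Time-resolved searchlight decoder with leave-one-run-out CV.

    Parameters
    ----------
    radius : sphere radius in voxels (3 reproduces the main analysis;
        4 the control with decreased accuracies).
    C : SVM regularization constant.
    bins : iterable of 1-based time-bins to map (default all 20).
    min_in_mask_fraction : minimum fraction of sphere voxels inside the
        mask for a center to be scored.

    Attributes (after ``fit``)
    --------------------------
    accuracy_maps_ : dict mapping bin -> 3D accuracy grid (NaN at invalid
        centers).
    """

    def __init__(
        self,
        radius: float = 3.0,
        C: float = 1.0,
        bins: tuple[int, ...] | None = None,
        min_in_mask_fraction: float = 0.5,
    ):
        self.radius = radius
        self.C = C
        self.bins = bins
        self.min_in_mask_fraction = min_in_mask_fraction

    def get_params(self, deep: bool = True) -> dict:
        return {
            "radius": self.radius,
            "C": self.C,
            "bins": self.bins,
            "min_in_mask_fraction": self.min_in_mask_fraction,
        }

    def set_params(self, **params) -> "SearchlightDecoder":
        known = self.get_params()
        for k, v in params.items():
            if k not in known:
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    @property
    def spec(self) -> SearchlightSpec:
        return SearchlightSpec(
            radius=self.radius, C=self.C, min_in_mask_fraction=self.min_in_mask_fraction
        )

    def fit(self, betas: list[BetaMaps], mask: np.ndarray | None = None) -> "SearchlightDecoder":
        bins = self.bins if self.bins is not None else tuple(range(1, N_BINS + 1))
        self.accuracy_maps_ = {
            b: accuracy_map(betas, mask=mask, spec=self.spec, bin_1based=b) for b in bins
        }
        return self

    def to_4d(self) -> np.ndarray:
        """Stack fitted maps into (x, y, z, n_bins) in ascending bin order."""
        bins = sorted(self.accuracy_maps_)
        return np.stack([self.accuracy_maps_[b] for b in bins], axis=-1)
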