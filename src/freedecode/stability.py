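"""Temporal pattern-stability analyses.

Two complementary views of how stable the choice-predictive pattern is
over peristimulus time:

* decoding on *bin-combined* vectors — adjacent time-bins are either
  averaged (length N) or concatenated (length k*N) in windows of k = 2, 3
  or 4 bins tiled backward from the decision bin, and the leave-one-run-
  out decoder is rerun on the combined vectors; and
* the correlation of each bin's pattern with the preceding bin's pattern
  (per subject, condition and run, then averaged), a direct measure of
  pattern persistence.

Both are computed at a single searchlight location: the center with the
highest *group-mean* accuracy at the bin directly preceding the decision
(deliberately not re-selected per subject).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .glm import DECISION_BIN, N_BINS, BetaMaps
from .searchlight import PatternVectors, SearchlightSpec, extract_patterns, loro_decode

__all__ = [
    "CombineSpec",
    "combine_bins",
    "decode_combined",
    "adjacent_bin_similarity",
    "best_group_center",
    "StabilityAnalysis",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CombineSpec:
    """How to combine adjacent time-bins into one vector."""

    mode: str = "concatenate"  # or "average"
    k: int = 2
    anchor: int = DECISION_BIN

    def __post_init__(self) -> None:
        if self.mode not in ("average", "concatenate"):
            raise ValueError("mode must be 'average' or 'concatenate'")
        if self.k < 2:
            raise ValueError("k must be >= 2")


def _windows(spec: CombineSpec, available: list[int]) -> list[tuple[int, int]]:
    """k-bin windows tiling backward from the anchor; incomplete ones dropped.

    Bins above the anchor are tiled forward symmetrically so post-decision
    windows exist when post-decision bins are supplied.
    """
    lo, hi = min(available), max(available)
    out = []
    end = spec.anchor
    while end - spec.k + 1 >= lo:
        out.append((end - spec.k + 1, end))
        end -= spec.k
    start = spec.anchor + 1
    while start + spec.k - 1 <= hi:
        out.append((start, start + spec.k - 1))
        start += spec.k
    dropped = set(available) - {b for s, e in out for b in range(s, e + 1)}
    if dropped:
        logger.info("bins %s not covered by complete %d-bin windows; dropped",
                    sorted(dropped), spec.k)
    return sorted(out)


def combine_bins(
    patterns_by_bin: dict[int, PatternVectors], spec: CombineSpec
) -> dict[tuple[int, int], PatternVectors]:
    """Combine per-bin pattern vectors into per-window vectors.

    Averaging keeps length N; concatenation stacks the k bins into length
    k*N. Rows (condition, run samples) are combined independently.
    """
    bins = sorted(patterns_by_bin)
    out: dict[tuple[int, int], PatternVectors] = {}
    for start, end in _windows(spec, bins):
        window = list(range(start, end + 1))
        if any(b not in patterns_by_bin for b in window):
            logger.info("window %s incomplete; dropped", (start, end))
            continue
        mats = [patterns_by_bin[b].X for b in window]
        ref = patterns_by_bin[window[0]]
        if spec.mode == "average":
            X = np.mean(mats, axis=0)
        else:
            X = np.concatenate(mats, axis=1)
        out[(start, end)] = PatternVectors(X=X, y=ref.y.copy(), runs=ref.runs.copy())
    return out


def decode_combined(
    combined: dict[tuple[int, int], PatternVectors], spec: SearchlightSpec
) -> dict[tuple[int, int], float]:
    """Leave-one-run-out accuracy for each combined window."""
    return {w: loro_decode(pv, spec) for w, pv in combined.items()}


def adjacent_bin_similarity(
    subject_patterns: list[dict[int, PatternVectors]], method: str = "pearson"
) -> dict[tuple[int, int], float]:
    """Correlation of each bin's pattern with the preceding bin's.

    Computed per subject, per condition, per run, then averaged across
    all of them; zero-variance vectors skip their pair with a log entry.
    Returns {(b-1, b): mean r}.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError("method must be 'pearson' or 'spearman'")
    bins = sorted(subject_patterns[0])
    if len(bins) < 2:
        raise ValueError("need at least 2 bins")
    out: dict[tuple[int, int], float] = {}
    for prev, cur in zip(bins[:-1], bins[1:]):
        rs = []
        for pats in subject_patterns:
            a_all, b_all = pats[prev], pats[cur]
            for i in range(len(a_all.X)):  # one row per (condition, run)
                a, b = a_all.X[i], b_all.X[i]
                if np.std(a) == 0 or np.std(b) == 0:
                    logger.info("zero-variance vector at bins (%d,%d); pair skipped", prev, cur)
                    continue
                if method == "pearson":
                    rs.append(stats.pearsonr(a, b).statistic)
                else:
                    rs.append(stats.spearmanr(a, b).statistic)
        out[(prev, cur)] = float(np.mean(rs)) if rs else float("nan")
    return out


def best_group_center(group_mean_map: np.ndarray) -> tuple[int, int, int]:
    """Voxel with the highest group-mean accuracy (NaN-safe)."""
    if not np.isfinite(group_mean_map).any():
        raise ValueError("group map is all-NaN")
    flat = np.nanargmax(group_mean_map)
    return tuple(int(i) for i in np.unravel_index(flat, group_mean_map.shape))


class StabilityAnalysis:
    """Bin-combination decoding and adjacent-bin pattern correlation.

    The searchlight location is fixed across subjects: the center
    maximizing the group-mean accuracy map at the bin directly preceding
    the decision (bin 9, lag -1.5 s). Patterns at that center are then
    extracted from every subject's own estimates.

    Parameters
    ----------
    ks : window sizes for bin combination.
    modes : 'average' and/or 'concatenate'.
    radius, C : searchlight sphere and classifier settings.

    Attributes (after ``fit``)
    --------------------------
    center_ : the shared searchlight center.
    combined_accuracy_ : {(mode, k): {window: mean accuracy across subjects}}.
    similarity_ : {(b-1, b): mean correlation}.
    per_bin_accuracy_ : {bin: mean single-bin accuracy at the center}.
    """

    def __init__(
        self,
        ks: tuple[int, ...] = (2, 3, 4),
        modes: tuple[str, ...] = ("average", "concatenate"),
        radius: float = 3.0,
        C: float = 1.0,
        similarity: str = "pearson",
    ):
        self.ks = ks
        self.modes = modes
        self.radius = radius
        self.C = C
        self.similarity = similarity

    def get_params(self, deep: bool = True) -> dict:
        return {
            "ks": self.ks,
            "modes": self.modes,
            "radius": self.radius,
            "C": self.C,
            "similarity": self.similarity,
        }

    def set_params(self, **params) -> "StabilityAnalysis":
        known = self.get_params()
        for k, v in params.items():
            if k not in known:
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(
        self,
        subject_betas: list[list[BetaMaps]],
        group_mean_map: np.ndarray,
        center: tuple[int, int, int] | None = None,
    ) -> "StabilityAnalysis":
        spec = SearchlightSpec(radius=self.radius, C=self.C)
        self.center_ = center if center is not None else best_group_center(group_mean_map)
        per_subject: list[dict[int, PatternVectors]] = []
        for betas in subject_betas:
            per_subject.append(
                {
                    b: extract_patterns(betas, self.center_, spec, b)
                    for b in range(1, N_BINS + 1)
                }
            )
        self.per_bin_accuracy_ = {
            b: float(np.mean([loro_decode(p[b], spec) for p in per_subject]))
            for b in range(1, N_BINS + 1)
        }
        self.combined_accuracy_ = {}
        for mode in self.modes:
            for k in self.ks:
                cspec = CombineSpec(mode=mode, k=k)
                per_window: dict[tuple[int, int], list[float]] = {}
                for pats in per_subject:
                    accs = decode_combined(combine_bins(pats, cspec), spec)
                    for w, a in accs.items():
                        per_window.setdefault(w, []).append(a)
                self.combined_accuracy_[(mode, k)] = {
                    w: float(np.mean(v)) for w, v in sorted(per_window.items())
                }
        self.similarity_ = adjacent_bin_similarity(per_subject, method=self.similarity)
        return self
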