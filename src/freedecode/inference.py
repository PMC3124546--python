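"""Group-level statistics on accuracy maps and univariate controls.

Subject accuracy maps are smoothed (3 mm FWHM), restricted to the voxels
shared by all subjects, and tested per voxel against chance (50%) with a
one-sided one-sample t-test across subjects, separately for each
time-bin. Significance is controlled with Benjamini-Hochberg FDR at
q = .05 over in-mask voxels, and surviving voxels are grouped into
26-connected clusters of at least 5 voxels.

The univariate control contrasts left vs right FIR estimates per voxel
(two-sided, liberal p < .001 uncorrected) — on the generator's zero-mean
templates this should find nothing, which is exactly the point: the
choice lives in the fine-grained pattern, not in the mean signal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats
from statsmodels.stats.multitest import fdrcorrection

__all__ = [
    "Cluster",
    "GroupResult",
    "smooth_map",
    "group_test",
    "fdr_cluster_threshold",
    "univariate_contrast",
    "percent_signal_timecourse",
    "GroupAccuracyTest",
]

logger = logging.getLogger(__name__)

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))
CONNECTIVITY_26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class Cluster:
    size: int
    peak_stat: float
    peak_value: float
    peak_ijk: tuple[int, int, int]


@dataclass
class GroupResult:
    """Group statistics for one time-bin."""

    bin: int
    t: np.ndarray
    p: np.ndarray
    thresholded: np.ndarray
    clusters: list[Cluster] = field(default_factory=list)


def smooth_map(grid: np.ndarray, fwhm_mm: float, voxel_size_mm: float = 1.0) -> np.ndarray:
    """Gaussian smoothing with NaN-aware normalized convolution.

    NaN voxels (outside valid searchlight centers) neither receive nor
    contribute weight; they remain NaN in the output. ``fwhm_mm == 0`` is
    the identity.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm must be >= 0")
    valid = np.isfinite(grid)
    if not valid.any():
        raise ValueError("cannot smooth an all-NaN map")
    if fwhm_mm == 0:
        return grid.copy()
    sigma = fwhm_mm * FWHM_TO_SIGMA / voxel_size_mm
    filled = np.where(valid, grid, 0.0)
    num = ndimage.gaussian_filter(filled, sigma)
    den = ndimage.gaussian_filter(valid.astype(float), sigma)
    out = np.full_like(grid, np.nan, dtype=float)
    np.divide(num, den, out=out, where=valid & (den > 0))
    return out


def shared_mask(maps: list[np.ndarray]) -> np.ndarray:
    """Voxels with finite values in every subject's map."""
    return np.logical_and.reduce([np.isfinite(m) for m in maps])


def group_test(
    subject_maps: list[np.ndarray],
    chance: float = 0.5,
    mask: np.ndarray | None = None,
    alternative: str = "greater",
) -> tuple[np.ndarray, np.ndarray]:
    """Per-voxel one-sample t-test of subject maps against ``chance``.

    Returns (t, p) grids, NaN outside the shared mask. Voxels with zero
    between-subject variance get p = 0 when the mean beats chance, else
    p = 1 (logged), so degenerate voxels cannot silently vanish.
    """
    if len(subject_maps) < 3:
        raise ValueError("group test needs at least 3 subjects")
    if mask is None:
        mask = shared_mask(subject_maps)
    data = np.stack(subject_maps)  # (n_subjects, x, y, z)
    n = data.shape[0]
    mean = data.mean(axis=0)
    sd = data.std(axis=0, ddof=1)
    t = np.full(mask.shape, np.nan)
    p = np.full(mask.shape, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_all = (mean - chance) / (sd / np.sqrt(n))
    ok = mask & (sd > 0)
    t[ok] = t_all[ok]
    if alternative == "greater":
        p[ok] = stats.t.sf(t[ok], df=n - 1)
    elif alternative == "two-sided":
        p[ok] = 2 * stats.t.sf(np.abs(t[ok]), df=n - 1)
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    degenerate = mask & (sd == 0)
    if degenerate.any():
        logger.info("%d voxels with zero between-subject variance", degenerate.sum())
        above = degenerate & (mean > chance)
        t[degenerate] = np.where(above[degenerate], np.inf, 0.0)
        p[degenerate] = np.where(above[degenerate], 0.0, 1.0)
    return t, p


def label_clusters(binary: np.ndarray, connectivity: np.ndarray = CONNECTIVITY_26):
    """26-connected component labeling of a binary 3D grid."""
    return ndimage.label(binary, structure=connectivity)


def fdr_cluster_threshold(
    p: np.ndarray,
    mask: np.ndarray | None = None,
    q: float = 0.05,
    extent: int = 5,
    stat: np.ndarray | None = None,
    value: np.ndarray | None = None,
    bin_1based: int = 0,
) -> GroupResult:
    """Benjamini-Hochberg FDR over in-mask voxels + cluster-extent filter.

    ``stat``/``value`` (e.g. the t grid and the mean accuracy grid) are
    used to report cluster peaks. Clusters smaller than ``extent`` voxels
    under 26-connectivity are removed.
    """
    if mask is None:
        mask = np.isfinite(p)
    pv = p[mask]
    if pv.size and (np.nanmin(pv) < 0 or np.nanmax(pv) > 1):
        raise ValueError("p-values must lie in [0, 1]")
    pv = np.where(np.isfinite(pv), pv, 1.0)  # untestable voxels can never survive
    reject = np.zeros(p.shape, dtype=bool)
    if pv.size:
        rej, _ = fdrcorrection(pv, alpha=q, method="indep")
        reject[mask] = rej
    labels, n_labels = label_clusters(reject)
    clusters: list[Cluster] = []
    keep = np.zeros_like(reject)
    for lab in range(1, n_labels + 1):
        where = labels == lab
        size = int(where.sum())
        if size < extent:
            continue
        keep |= where
        peak_grid = stat if stat is not None else (value if value is not None else p)
        coords = np.argwhere(where)
        vals = peak_grid[where]
        peak_i = int(np.nanargmax(vals)) if stat is not None or value is not None else int(
            np.nanargmin(vals)
        )
        ijk = tuple(int(c) for c in coords[peak_i])
        clusters.append(
            Cluster(
                size=size,
                peak_stat=float(stat[ijk]) if stat is not None else float("nan"),
                peak_value=float(value[ijk]) if value is not None else float("nan"),
                peak_ijk=ijk,
            )
        )
    t_grid = stat if stat is not None else np.full(p.shape, np.nan)
    return GroupResult(
        bin=bin_1based,
        t=t_grid,
        p=p,
        thresholded=keep,
        clusters=sorted(clusters, key=lambda c: -c.size),
    )


def univariate_contrast(
    left_maps: list[np.ndarray],
    right_maps: list[np.ndarray],
    mask: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Paired left-vs-right contrast across subjects at one bin.

    Returns (t, p) grids of the two-sided paired t-test on per-subject
    left minus right estimates; the conventional screen applies the
    liberal threshold p < .001 uncorrected.
    """
    if len(left_maps) != len(right_maps):
        raise ValueError("need paired left/right maps")
    diffs = [l - r for l, r in zip(left_maps, right_maps)]
    return group_test(diffs, chance=0.0, mask=mask, alternative="two-sided")


def percent_signal_timecourse(
    subject_betas: list[np.ndarray],
    baseline: float,
) -> np.ndarray:
    """Percent-signal time course from FIR estimates at one voxel.

    ``subject_betas``: per subject, an array (n_conditions, 20) of FIR
    estimates at the chosen voxel (already averaged over runs). Returns
    (n_conditions, 20): 100 * estimate / baseline averaged across
    subjects.
    """
    if baseline <= 0:
        raise ValueError("baseline must be positive")
    stack = np.stack(subject_betas)  # (n_subj, n_cond, 20)
    return 100.0 * stack.mean(axis=0) / baseline


class GroupAccuracyTest:
    """Smoothing + group t-test + FDR/cluster thresholding per time-bin.

    Parameters
    ----------
    fwhm_mm : Gaussian smoothing kernel FWHM applied to each subject map.
    chance : accuracy under the null (0.5 for two balanced choices).
    q : FDR level.
    extent : minimum cluster size in voxels.

    Attributes (after ``fit``)
    --------------------------
    results_ : dict bin -> GroupResult.
    mask_ : shared-voxel mask used for inference.
    """

    def __init__(
        self, fwhm_mm: float = 3.0, chance: float = 0.5, q: float = 0.05, extent: int = 5
    ):
        self.fwhm_mm = fwhm_mm
        self.chance = chance
        self.q = q
        self.extent = extent

    def get_params(self, deep: bool = True) -> dict:
        return {
            "fwhm_mm": self.fwhm_mm,
            "chance": self.chance,
            "q": self.q,
            "extent": self.extent,
        }

    def set_params(self, **params) -> "GroupAccuracyTest":
        known = self.get_params()
        for k, v in params.items():
            if k not in known:
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, subject_maps_by_bin: dict[int, list[np.ndarray]]) -> "GroupAccuracyTest":
        """``subject_maps_by_bin``: bin -> list of per-subject 3D accuracy maps."""
        smoothed = {
            b: [smooth_map(m, self.fwhm_mm) for m in maps]
            for b, maps in subject_maps_by_bin.items()
        }
        first = next(iter(smoothed.values()))
        self.mask_ = shared_mask(first)
        for maps in smoothed.values():
            self.mask_ &= shared_mask(maps)
        self.results_ = {}
        for b, maps in sorted(smoothed.items()):
            t, p = group_test(maps, chance=self.chance, mask=self.mask_)
            mean_map = np.stack(maps).mean(axis=0)
            self.results_[b] = fdr_cluster_threshold(
                p,
                mask=self.mask_,
                q=self.q,
                extent=self.extent,
                stat=t,
                value=mean_map,
                bin_1based=b,
            )
        return self
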