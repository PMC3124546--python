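"""Searchlight geometry, LORO decoding, and accuracy-map contracts."""

import itertools

import numpy as np
import pytest
from scipy import optimize

from freedecode.glm import FIRGLM
from freedecode.searchlight import (
    LABELS,
    PatternVectors,
    SearchlightSpec,
    _fold_predict,
    accuracy_map,
    extract_patterns,
    loro_decode,
    loro_folds,
    sphere_offsets,
)
from freedecode.synth import BehaviorConfig, SignalConfig, simulate_behavior, simulate_subject_bold


def brute_force_offsets(radius):
    r = int(np.floor(radius))
    out = []
    for dx, dy, dz in itertools.product(range(-r, r + 1), repeat=3):
        if dx * dx + dy * dy + dz * dz <= radius * radius:
            out.append((dx, dy, dz))
    return sorted(out)


class TestSphere:
    @pytest.mark.parametrize("radius,count", [(1, 7), (2, 33), (3, 123), (4, 257)])
    def test_offset_count_matches_lattice_enumeration(self, radius, count):
        offs = sphere_offsets(radius)
        assert len(offs) == count
        assert [tuple(o) for o in offs] == brute_force_offsets(radius)

    def test_offsets_closed_under_symmetry(self):
        offs = {tuple(o) for o in sphere_offsets(3)}
        assert (0, 0, 0) in offs
        for o in offs:
            assert tuple(-np.array(o)) in offs
            for perm in itertools.permutations(o):
                assert perm in offs

    def test_radius_below_one_rejected(self):
        with pytest.raises(ValueError):
            sphere_offsets(0.5)


@pytest.fixture(scope="module")
def fitted_glm(small_layout, events, signal_cfg):
    runs = simulate_subject_bold(events, small_layout, signal_cfg)
    return FIRGLM().fit(runs, events)


class TestExtract:
    def test_two_vectors_per_run_at_interior_center(self, fitted_glm):
        pv = extract_patterns(fitted_glm.betas_, (5, 5, 5), SearchlightSpec(), 9)
        assert len(pv.X) == 2 * 10  # 2 conditions x 10 runs
        assert pv.n_features == 123
        assert set(pv.y) == {0, 1}
        assert LABELS == ("left", "right")

    def test_low_mask_fraction_center_rejected(self, fitted_glm):
        # mask radius 5 on a 12^3 grid: a center at the mask edge keeps
        # fewer than half of the 123 sphere voxels
        mask = fitted_glm.betas_[0].mask
        edge = tuple(np.argwhere(mask)[0])
        with pytest.raises(ValueError, match="fraction"):
            extract_patterns(fitted_glm.betas_, edge, SearchlightSpec(), 9)

    def test_center_outside_mask_rejected(self, fitted_glm):
        with pytest.raises(ValueError, match="outside"):
            extract_patterns(fitted_glm.betas_, (0, 0, 0), SearchlightSpec(), 9)


def _patterns(X, n_runs):
    y = np.tile([0, 1], n_runs)
    runs = np.repeat(np.arange(n_runs), 2)
    return PatternVectors(X=X, y=y, runs=runs)


class TestLoro:
    def test_fold_structure_each_run_held_out_once(self):
        runs = np.repeat(np.arange(10), 2)
        folds = loro_folds(runs)
        assert len(folds) == 10
        held = [int(test[0]) for _, test in folds]
        assert sorted(held) == list(range(10))
        for train, test in folds:
            assert set(train) | set(test) == set(range(10))
            assert not set(train) & set(test)

    def test_separable_templates_decode_perfectly(self):
        rng = np.random.default_rng(0)
        a = np.zeros(20)
        a[:10] = 1
        b = 1 - a
        X = np.stack([(a if i % 2 == 0 else b) + 1e-3 * rng.standard_normal(20)
                      for i in range(16)])
        assert loro_decode(_patterns(X, 8), SearchlightSpec()) == 1.0

    def test_shuffled_labels_decode_at_chance(self):
        """Within-run label shuffling over many seeds averages to 50%."""
        rng = np.random.default_rng(1)
        accs = []
        for _ in range(500):
            X = rng.standard_normal((12, 8))
            pv = _patterns(X, 6)
            swap = rng.random(6) < 0.5  # relabel conditions within runs
            y = pv.y.copy()
            for r in np.flatnonzero(swap):
                y[2 * r : 2 * r + 2] = y[2 * r : 2 * r + 2][::-1]
            accs.append(loro_decode(PatternVectors(X=X, y=y, runs=pv.runs),
                                    SearchlightSpec()))
        assert np.mean(accs) == pytest.approx(0.5, abs=0.02)

    def test_per_fold_accuracy_on_half_grid(self):
        rng = np.random.default_rng(2)
        accs = {loro_decode(_patterns(rng.standard_normal((20, 5)), 10),
                            SearchlightSpec()) for _ in range(50)}
        grid = np.round(np.arange(0, 1.0001, 0.05), 10)
        for a in accs:
            assert np.any(np.isclose(a, grid))

    def test_needs_three_runs(self):
        rng = np.random.default_rng(3)
        with pytest.raises(ValueError, match="3 runs"):
            loro_decode(_patterns(rng.standard_normal((4, 5)), 2), SearchlightSpec())

    def test_degenerate_constant_patterns_score_half(self):
        X = np.ones((8, 5))
        assert loro_decode(_patterns(X, 4), SearchlightSpec()) == 0.5

    def test_fold_predictions_match_direct_qp_solver(self):
        """The linear max-margin fit agrees with a brute-force dual QP."""
        rng = np.random.default_rng(4)
        C = 1.0
        for trial in range(10):
            X_train = rng.standard_normal((10, 8)) + 0.5
            y_train = np.tile([0, 1], 5)
            X_test = rng.standard_normal((4, 8))
            got = _fold_predict(X_train, y_train, X_test, C)
            want = _qp_predict(X_train, y_train, X_test, C)
            assert np.array_equal(got, want), f"trial {trial}"


def _qp_predict(X, y, X_test, C):
    """Soft-margin SVM by direct dual quadratic optimization."""
    s = np.where(y == 1, 1.0, -1.0)
    K = X @ X.T
    n = len(y)

    def neg_dual(alpha):
        return 0.5 * alpha @ (K * np.outer(s, s)) @ alpha - alpha.sum()

    cons = {"type": "eq", "fun": lambda a: a @ s}
    res = optimize.minimize(
        neg_dual,
        np.full(n, 0.1),
        bounds=[(0, C)] * n,
        constraints=[cons],
        method="SLSQP",
        options={"maxiter": 500, "ftol": 1e-12},
    )
    alpha = res.x
    w = (alpha * s) @ X
    margin = (alpha > 1e-6) & (alpha < C - 1e-6)
    sv = margin if margin.any() else alpha > 1e-6
    b = float(np.mean(s[sv] - X[sv] @ w))
    return (X_test @ w + b > 0).astype(int)


class TestAccuracyMap:
    def test_map_grid_values_and_nan_outside_valid_centers(self, fitted_glm):
        amap = accuracy_map(fitted_glm.betas_, bin_1based=9)
        vals = amap[np.isfinite(amap)]
        assert vals.size > 100
        assert vals.min() >= 0 and vals.max() <= 1
        grid = np.round(np.arange(0, 1.0001, 0.05), 10)
        assert np.all(np.isclose(vals[:, None], grid[None, :]).any(axis=1))
        # centers outside the mask are never scored
        assert np.all(np.isnan(amap[~fitted_glm.betas_[0].mask]))

    def test_signal_is_spatially_specific(self, fitted_glm, small_layout):
        """Top-20 pre-decision centers concentrate within one radius of the
        informative region."""
        amap = accuracy_map(fitted_glm.betas_, bin_1based=9)
        flat = np.argsort(np.nan_to_num(amap, nan=-1.0).ravel())[::-1][:20]
        coords = np.array(np.unravel_index(flat, amap.shape)).T
        center = (np.array(small_layout.shape) - 1) / 2
        dist = np.linalg.norm(coords - center, axis=1)
        near = dist <= small_layout.region_radius + 3.0
        assert near.mean() >= 0.8

    def test_empty_mask_rejected(self, fitted_glm):
        with pytest.raises(ValueError, match="mask"):
            accuracy_map(fitted_glm.betas_, mask=np.zeros((12, 12, 12), bool))


class TestCalibration:
    def test_unpermuted_peak_beats_permutation_null(self):
        """Peak accuracy on signal-bearing data exceeds the 95th percentile
        of the within-run label-permutation null (200 permutations)."""
        from freedecode.synth import VolumeLayout

        layout = VolumeLayout(shape=(11, 11, 11), mask_radius=3.0, region_radius=2.0)
        cfg = BehaviorConfig(n_runs=10, seed=21)
        sig = SignalConfig(seed=21)
        ev = simulate_behavior(cfg)
        glm = FIRGLM().fit(simulate_subject_bold(ev, layout, sig), ev)
        spec = SearchlightSpec()
        n_runs = len(ev)
        pats = {}
        for c in map(tuple, np.argwhere(layout.mask)):
            try:
                pats[c] = extract_patterns(glm.betas_, c, spec, 9)
            except ValueError:
                continue
        assert len(pats) >= 10
        true_peak = max(loro_decode(pv, spec) for pv in pats.values())
        rng = np.random.default_rng(0)
        null_peaks = []
        while len(null_peaks) < 200:
            swap = rng.random(n_runs) < 0.5
            if swap.all() or not swap.any():
                continue  # identity-equivalent relabelings are not null draws
            peaks = []
            for pv in pats.values():
                y = pv.y.copy()
                for r in np.flatnonzero(swap):
                    y[2 * r : 2 * r + 2] = y[2 * r : 2 * r + 2][::-1]
                peaks.append(
                    loro_decode(PatternVectors(X=pv.X, y=y, runs=pv.runs), spec)
                )
            null_peaks.append(max(peaks))
        assert true_peak > np.percentile(null_peaks, 95)

    def test_no_post_decision_information(self, small_layout):
        """With the pattern vanishing at the decision, region accuracy at
        bins 11-20 averages to chance (several-subject aggregate)."""
        spec = SearchlightSpec()
        region_centers = [
            tuple(c)
            for c in np.argwhere(small_layout.informative_region)
        ]
        accs = []
        n_subj = 0
        seed = 0
        while n_subj < 5:
            seed += 1
            try:
                cfg = BehaviorConfig(n_runs=10, seed=300 + seed)
                sig = SignalConfig(seed=300 + seed)
                ev = simulate_behavior(cfg)
                glm = FIRGLM().fit(simulate_subject_bold(ev, small_layout, sig), ev)
                subj_accs = [
                    loro_decode(extract_patterns(glm.betas_, c, spec, b), spec)
                    for b in range(11, 21)
                    for c in region_centers
                ]
            except ValueError:  # unestimable bin or degenerate design: excluded
                continue
            n_subj += 1
            accs.extend(subj_accs)
        assert np.mean(accs) == pytest.approx(0.5, abs=0.02)
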