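"""Behavioral randomness statistics and screening rules."""

import itertools

import numpy as np
import pytest
from scipy import stats

from conftest import make_events
from freedecode.behavior import (
    ScreeningCriteria,
    choice_balance,
    fit_exponential_model,
    interrun_correlation,
    run_lengths,
    runs_test,
    runs_tests_by_run,
    screen_subject,
    sequence_length_histogram,
    subject_summary,
)


def events_from_choices(choices, run_id=0, gap=20.0):
    onsets = 15.0 + gap * np.arange(len(choices))
    return make_events(onsets, choices, run_id=run_id)


class TestBalance:
    def test_even_split_gives_zero_chi2(self):
        ev = events_from_choices(["left"] * 50 + ["right"] * 50)
        chi2, p = choice_balance([ev])
        assert chi2 == 0.0 and p == 1.0

    def test_sixty_forty_gives_chi2_of_four(self):
        ev = events_from_choices(["left"] * 60 + ["right"] * 40)
        chi2, p = choice_balance([ev])
        assert chi2 == pytest.approx(4.0)
        assert p == pytest.approx(stats.chi2.sf(4.0, df=1), abs=1e-12)
        assert p == pytest.approx(0.0455, abs=5e-4)


class TestSequenceLengths:
    def test_alternating_choices_are_all_length_one(self):
        ev = events_from_choices(["left", "right", "left", "right", "left"])
        assert sequence_length_histogram([ev]) == {1: 100.0}

    def test_mixed_lengths_counted_exactly(self):
        ev = events_from_choices(["left", "left", "right", "right", "right", "left"])
        hist = sequence_length_histogram([ev])
        assert hist == {
            1: pytest.approx(100 / 3),
            2: pytest.approx(100 / 3),
            3: pytest.approx(100 / 3),
        }

    def test_fair_choices_follow_geometric_law(self):
        """10^5 i.i.d. fair choices: 50% singles, 25% doubles, ... within 1%."""
        rng = np.random.default_rng(0)
        choices = np.where(rng.random(100_000) < 0.5, "left", "right")
        lengths = run_lengths(choices)
        values, counts = np.unique(lengths, return_counts=True)
        pct = dict(zip(values, 100 * counts / counts.sum()))
        for n in (1, 2, 3):
            assert pct[n] == pytest.approx(100 * 0.5**n, abs=1.0)

    def test_histogram_mass_accounts_for_every_trial(self, events):
        hist = sequence_length_histogram(events)
        assert sum(hist.values()) == pytest.approx(100.0, abs=1e-9)
        lengths = [n for t in events for n in run_lengths(t.choices)]
        assert sum(lengths) == sum(t.n_trials for t in events)


class TestExponentialFit:
    @pytest.mark.parametrize("c_true", [0.917, 0.5])
    def test_noiseless_recovery(self, c_true):
        x = np.arange(1, 9)
        hist = {int(i): 100.0 * c_true * np.exp(-c_true * i) for i in x}
        c, rmsd = fit_exponential_model(hist)
        assert c == pytest.approx(c_true, abs=1e-6)
        assert rmsd < 1e-8

    def test_fair_choice_histograms_give_plausible_decay(self):
        """Fitted c stays near ln 2 for simulated fair-choice histograms."""
        rng = np.random.default_rng(1)
        for _ in range(10):
            choices = np.where(rng.random(1500) < 0.5, "L", "R")
            lengths = run_lengths(choices)
            assert len(lengths) >= 500
            values, counts = np.unique(lengths, return_counts=True)
            hist = {int(v): 100 * c / counts.sum() for v, c in zip(values, counts)}
            c, _ = fit_exponential_model(hist)
            assert 0.5 <= c <= 1.1

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_exponential_model({1: 50.0, 2: 25.0})


class TestRunsTest:
    def test_alternation_is_too_many_runs(self):
        choices = np.array(["left", "right"] * 5)
        assert len(run_lengths(choices)) == 10  # maximum possible
        z, p = runs_test(choices)
        assert z > 0 and p < 0.05

    def test_clustering_is_too_few_runs(self):
        z, p = runs_test(np.array(["left"] * 5 + ["right"] * 5))
        assert z < 0

    def test_single_choice_is_undefined(self):
        with pytest.raises(ValueError):
            runs_test(np.array(["left"] * 6))
        results = runs_tests_by_run([events_from_choices(["left"] * 5)])
        assert results[0].skipped

    @pytest.mark.parametrize("n1,n2", [(3, 3), (4, 4), (5, 5), (6, 6), (4, 8), (5, 7)])
    def test_normal_approximation_tracks_exact_permutation_null(self, n1, n2):
        """The continuity-corrected normal p tracks the exact permutation p
        at n <= 12: within 0.05 in the rejection-relevant tail (exact
        p <= 0.05, where the approximation is conservative) and within 0.17
        everywhere (the worst case is the distribution center of unbalanced
        splits, where no decision is at stake)."""
        n = n1 + n2
        seqs = list(itertools.combinations(range(n), n1))
        counts = {}
        for pos in seqs:
            arr = np.zeros(n, int)
            arr[list(pos)] = 1
            r = 1 + int((arr[1:] != arr[:-1]).sum())
            counts[r] = counts.get(r, 0) + 1
        total = sum(counts.values())
        rs = np.array(sorted(counts))
        pmf = {r: counts[r] / total for r in rs}
        mu = 2 * n1 * n2 / n + 1
        for r_obs in rs:
            exact = sum(
                pr for r, pr in pmf.items() if abs(r - mu) >= abs(r_obs - mu) - 1e-9
            )
            seq = _sequence_with_runs(n1, n2, r_obs)
            z, p_norm = runs_test(np.array(seq))
            exact = min(exact, 1.0)
            if exact <= 0.05:
                assert p_norm == pytest.approx(exact, abs=0.04)
                assert p_norm >= exact - 1e-9  # conservative in the tail
            assert p_norm == pytest.approx(exact, abs=0.17)

    def test_type_one_error_controlled_after_bonferroni(self):
        """Rejection rate of corrected per-run tests stays below alpha."""
        rng = np.random.default_rng(2)
        alpha = 0.05
        rejections = 0
        n_subjects = 2000
        for _ in range(n_subjects):
            tables = []
            for run_id in range(4):
                choices = np.where(rng.random(11) < 0.5, "left", "right")
                tables.append(events_from_choices(choices, run_id=run_id))
            results = runs_tests_by_run(tables)
            if any((not r.skipped) and r.p_corrected < alpha for r in results):
                rejections += 1
        # discreteness + continuity correction make the test conservative
        assert rejections / n_subjects <= alpha


def _sequence_with_runs(n1, n2, r):
    """Binary sequence with n1 zeros, n2 ones and exactly r runs."""
    k0 = (r + 1) // 2  # runs of the first symbol
    k1 = r - k0
    if k0 > n1 or k1 > n2 or k1 < 1:
        k0, k1 = k1, k0
        first, second, c1, c2 = "right", "left", n2, n1
    else:
        first, second, c1, c2 = "left", "right", n1, n2
    blocks = []
    rem1, rem2 = c1, c2
    for i in range(k0 + k1):
        if i % 2 == 0:
            take = rem1 - (k0 - i // 2 - 1) if i // 2 == k0 - 1 else 1
            blocks += [first] * take
            rem1 -= take
        else:
            take = rem2 - (k1 - i // 2 - 1) if i // 2 == k1 - 1 else 1
            blocks += [second] * take
            rem2 -= take
    return blocks


class TestInterrun:
    def test_identical_runs_correlate_perfectly(self):
        a = events_from_choices(["left", "right", "left", "right"], run_id=0)
        b = events_from_choices(["left", "right", "left", "right"], run_id=1)
        pairs = interrun_correlation([a, b])
        assert pairs[0][2] == pytest.approx(1.0)

    def test_complementary_runs_anticorrelate_perfectly(self):
        a = events_from_choices(["left", "right", "left", "right"], run_id=0)
        b = events_from_choices(["right", "left", "right", "left"], run_id=1)
        assert interrun_correlation([a, b])[0][2] == pytest.approx(-1.0)

    def test_independent_fair_runs_average_to_zero(self):
        rng = np.random.default_rng(3)
        rs = []
        for _ in range(1000):
            a = events_from_choices(np.where(rng.random(10) < 0.5, "left", "right"), 0)
            b = events_from_choices(np.where(rng.random(10) < 0.5, "left", "right"), 1)
            pairs = interrun_correlation([a, b])
            if pairs:
                rs.append(pairs[0][2])
        assert np.mean(rs) == pytest.approx(0.0, abs=0.02)


class TestScreening:
    def test_slow_unbalanced_subject_is_excluded(self):
        """A 39/61 subject at a 58.4 s pace is excluded: the pace violates
        the 15-50 s bound outright, while 61/39 = 1.56 stays inside the
        formal 'more than twice as often' balance rule."""
        choices = (["left"] * 39) + (["right"] * 61)
        ev = events_from_choices(choices, gap=58.4)
        res = screen_subject([ev])
        assert not res.passed
        assert any("duration" in r for r in res.reasons)
        assert res.balance_ratio == pytest.approx(61 / 39)
        assert res.mean_duration == pytest.approx(58.4)
        # a split beyond 2:1 at the same pace fails both rules
        res2 = screen_subject(
            [events_from_choices(["left"] * 25 + ["right"] * 75, gap=58.4)]
        )
        assert len(res2.reasons) == 2

    def test_balanced_study_pace_passes(self):
        choices = ["left", "right"] * 50
        ev = events_from_choices(choices, gap=29.7)
        res = screen_subject([ev])
        assert res.passed and res.reasons == []

    def test_ratio_exactly_two_is_not_excluded(self):
        choices = ["left"] * 66 + ["right"] * 33
        ev = events_from_choices(choices, gap=30.0)
        res = screen_subject([ev])
        assert res.balance_ratio == pytest.approx(2.0)
        assert res.passed

    def test_screening_monotone_in_imbalance(self):
        """Making a failing subject's balance more extreme never rescues it."""
        for n_left in range(0, 34):  # at most 33 of 100 -> ratio > 2
            choices = ["left"] * n_left + ["right"] * (100 - n_left)
            ev = events_from_choices(choices, gap=30.0)
            assert not screen_subject([ev]).passed

    def test_invalid_criteria_rejected(self):
        with pytest.raises(ValueError):
            ScreeningCriteria(max_balance_ratio=1.0)


def test_subject_summary_is_consistent(events):
    s = subject_summary(events)
    assert s["left_pct"] + s["right_pct"] == pytest.approx(100.0)
    assert sum(s["sequence_histogram"].values()) == pytest.approx(100.0)
    assert 15.0 <= s["mean_duration_s"] <= 50.0
    assert len(s["runs_tests"]) == len(events)
    assert len(s["interrun_correlations"]) <= len(events) - 1
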