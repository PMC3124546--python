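"""Behavioral randomness statistics and subject screening.

Implements the behavioral battery applied to the self-paced choice
sequences: chi-square balance of left vs right, the histogram of
same-choice sequence lengths with its exponential fit
f(x) = 100*c*exp(-c*x), a Wald-Wolfowitz runs test per run (Bonferroni-
corrected across a subject's runs), Pearson correlations between the
choice sequences of consecutive runs, and the screening rule that
excludes subjects with a >2:1 choice imbalance or a mean inter-decision
interval outside 15-50 s.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize, stats

from .synth import EventTable

__all__ = [
    "ScreeningCriteria",
    "RunsTestResult",
    "ScreeningResult",
    "choice_balance",
    "run_lengths",
    "sequence_length_histogram",
    "fit_exponential_model",
    "runs_test",
    "interrun_correlation",
    "screen_subject",
    "subject_summary",
]


@dataclass(frozen=True)
class ScreeningCriteria:
    """Exclusion rules: choice-balance ratio and mean trial-duration bounds."""

    max_balance_ratio: float = 2.0
    duration_bounds: tuple[float, float] = (15.0, 50.0)

    def __post_init__(self) -> None:
        if self.max_balance_ratio <= 1:
            raise ValueError("balance ratio must exceed 1")
        lo, hi = self.duration_bounds
        if not (0 < lo < hi):
            raise ValueError("duration bounds must be positive and ordered")


@dataclass
class RunsTestResult:
    run_id: int
    n_runs_observed: int
    z: float
    p: float
    p_corrected: float
    skipped: bool = False
    reason: str = ""


@dataclass
class ScreeningResult:
    passed: bool
    reasons: list[str] = field(default_factory=list)
    balance_ratio: float = float("nan")
    mean_duration: float = float("nan")


def _all_choices(events: Sequence[EventTable]) -> list[np.ndarray]:
    return [t.choices for t in events]


def choice_balance(events: Sequence[EventTable]) -> tuple[float, float]:
    """Goodness-of-fit chi-square (df = 1) of left/right counts vs 50/50."""
    choices = np.concatenate(_all_choices(events))
    if choices.size < 2:
        raise ValueError("need at least 2 trials")
    n_left = int((choices == "left").sum())
    n_right = choices.size - n_left
    chi2, p = stats.chisquare([n_left, n_right])
    return float(chi2), float(p)


def run_lengths(choices: np.ndarray) -> list[int]:
    """Lengths of maximal same-choice stretches in one sequence."""
    if len(choices) == 0:
        return []
    switches = np.flatnonzero(choices[1:] != choices[:-1])
    bounds = np.concatenate([[-1], switches, [len(choices) - 1]])
    return list(np.diff(bounds).astype(int))


def sequence_length_histogram(
    events: Sequence[EventTable], span_runs: bool = False
) -> dict[int, float]:
    """Percent of same-choice sequences of each length before a switch.

    By default run boundaries break sequences (a stretch cannot span two
    runs); set ``span_runs`` to pool the whole experiment as one sequence.
    """
    if span_runs:
        lengths = run_lengths(np.concatenate(_all_choices(events)))
    else:
        lengths = [n for t in events for n in run_lengths(t.choices)]
    if not lengths:
        raise ValueError("no trials")
    values, counts = np.unique(lengths, return_counts=True)
    total = counts.sum()
    return {int(v): 100.0 * c / total for v, c in zip(values, counts)}


def fit_exponential_model(histogram: dict[int, float]) -> tuple[float, float]:
    """Least-squares fit of f(x) = 100*c*exp(-c*x) to the length histogram.

    Returns the decay constant c and the root-mean-square deviation
    between fit and histogram. A fitted c near ln(2) = 0.693 is what
    i.i.d. fair choices (geometric run lengths) produce.
    """
    if len(histogram) < 3:
        raise ValueError("need at least 3 histogram points")
    x = np.array(sorted(histogram), dtype=float)
    y = np.array([histogram[int(v)] for v in x], dtype=float)

    def f(x, c):
        return 100.0 * c * np.exp(-c * x)

    try:
        (c,), _ = optimize.curve_fit(f, x, y, p0=[0.7], maxfev=10000)
    except RuntimeError as err:  # pragma: no cover - pathological inputs
        raise RuntimeError(f"exponential fit did not converge: {err}") from err
    rmsd = float(np.sqrt(np.mean((f(x, c) - y) ** 2)))
    return float(c), rmsd


def runs_test(choices: np.ndarray) -> tuple[float, float]:
    """Wald-Wolfowitz runs test of a binary sequence, two-sided.

    Normal approximation with continuity correction:
    mu = 2*n1*n2/n + 1, var = 2*n1*n2*(2*n1*n2 - n) / (n^2 * (n - 1)).
    Raises if only one choice occurs (the test is undefined).
    """
    choices = np.asarray(choices)
    n1 = int((choices == choices[0]).sum())
    n2 = len(choices) - n1
    if n1 == 0 or n2 == 0:
        raise ValueError("runs test undefined: only one choice present")
    n = n1 + n2
    observed = len(run_lengths(choices))
    mu = 2.0 * n1 * n2 / n + 1.0
    var = 2.0 * n1 * n2 * (2.0 * n1 * n2 - n) / (n**2 * (n - 1.0))
    if var <= 0:
        raise ValueError("degenerate variance in runs test")
    diff = observed - mu
    cc = 0.5 if abs(diff) > 0.5 else abs(diff)  # continuity correction toward the mean
    z = (abs(diff) - cc) / np.sqrt(var) * np.sign(diff) if diff != 0 else 0.0
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(min(p, 1.0))


def runs_tests_by_run(events: Sequence[EventTable]) -> list[RunsTestResult]:
    """Per-run randomness tests, Bonferroni-corrected across a subject's runs."""
    testable = []
    results = []
    for table in events:
        choices = table.choices
        if np.unique(choices).size < 2:
            results.append(
                RunsTestResult(
                    run_id=table.run_id,
                    n_runs_observed=len(run_lengths(choices)),
                    z=float("nan"),
                    p=float("nan"),
                    p_corrected=float("nan"),
                    skipped=True,
                    reason="only one choice in run",
                )
            )
            continue
        z, p = runs_test(choices)
        res = RunsTestResult(
            run_id=table.run_id,
            n_runs_observed=len(run_lengths(choices)),
            z=z,
            p=p,
            p_corrected=p,
        )
        testable.append(res)
        results.append(res)
    m = len(testable)
    for res in testable:
        res.p_corrected = min(1.0, res.p * m)
    return results


def interrun_correlation(events: Sequence[EventTable]) -> list[tuple[int, int, float, float]]:
    """Pearson correlation of consecutive runs' choice sequences.

    Choices are coded +/-1 and each pair truncated to the shorter run;
    zero-variance runs skip their pair. Returns (run_i, run_j, r, p)
    tuples.
    """
    if len(events) < 2:
        raise ValueError("need at least 2 runs")
    out = []
    for a, b in zip(events[:-1], events[1:]):
        xa = np.where(a.choices == "left", 1.0, -1.0)
        xb = np.where(b.choices == "left", 1.0, -1.0)
        n = min(len(xa), len(xb))
        xa, xb = xa[:n], xb[:n]
        if np.std(xa) == 0 or np.std(xb) == 0:
            continue
        r = stats.pearsonr(xa, xb)
        out.append((a.run_id, b.run_id, float(r.statistic), float(r.pvalue)))
    return out


def screen_subject(
    events: Sequence[EventTable], criteria: ScreeningCriteria = ScreeningCriteria()
) -> ScreeningResult:
    """Apply the exclusion rules to one subject's event tables.

    Fails when one option was chosen *more than* twice as often as the
    other (a ratio of exactly 2 still passes), or when the mean
    inter-decision interval falls outside 15-50 s.
    """
    choices = np.concatenate(_all_choices(events))
    if choices.size < 1:
        raise ValueError("no trials")
    n_left = int((choices == "left").sum())
    n_right = choices.size - n_left
    if min(n_left, n_right) == 0:
        ratio = float("inf")
    else:
        ratio = max(n_left, n_right) / min(n_left, n_right)
    gaps = np.concatenate([np.diff(t.onsets) for t in events if t.n_trials >= 2])
    mean_duration = float(gaps.mean()) if gaps.size else float("nan")
    reasons = []
    if ratio > criteria.max_balance_ratio:
        reasons.append(
            f"unbalanced choices: ratio {ratio:.2f} > {criteria.max_balance_ratio}"
        )
    lo, hi = criteria.duration_bounds
    if not (lo <= mean_duration <= hi):
        reasons.append(
            f"mean trial duration {mean_duration:.1f} s outside [{lo}, {hi}] s"
        )
    return ScreeningResult(
        passed=not reasons,
        reasons=reasons,
        balance_ratio=ratio,
        mean_duration=mean_duration,
    )


def subject_summary(events: Sequence[EventTable]) -> dict:
    """One subject's behavioral summary row (percentages, balance test,
    durations, screening, randomness tests)."""
    choices = np.concatenate(_all_choices(events))
    n = choices.size
    n_left = int((choices == "left").sum())
    chi2, p = choice_balance(events)
    gaps = np.concatenate([np.diff(t.onsets) for t in events if t.n_trials >= 2])
    hist = sequence_length_histogram(events)
    screening = screen_subject(events)
    return {
        "n_trials": int(n),
        "left_pct": 100.0 * n_left / n,
        "right_pct": 100.0 * (n - n_left) / n,
        "balance_chi2": chi2,
        "balance_p": p,
        "mean_duration_s": float(gaps.mean()),
        "sd_duration_s": float(gaps.std(ddof=1)),
        "sequence_histogram": hist,
        "screening_passed": screening.passed,
        "screening_reasons": screening.reasons,
        "runs_tests": runs_tests_by_run(events),
        "interrun_correlations": interrun_correlation(events) if len(events) > 1 else [],
    }
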