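"""Small statistical kernel used by the other modules.

Hand-rolled Welch t and Wilcoxon rank-sum statistics (the latter exact
for small samples, normal-approximated with midranks, tie correction and
continuity correction otherwise); reference distributions come from
scipy.  Kept deliberately independent of scipy.stats.ttest_ind /
mannwhitneyu so those can serve as cross-checks in the test suite.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import norm as _norm
from scipy.stats import rankdata as _rankdata
from scipy.stats import t as _t_dist

_ALTERNATIVES = ("greater", "less", "two-sided")

#: combined-n ceiling for exhaustive combination enumeration (handles ties)
_EXACT_ENUM_N = 20
#: combined-n ceiling for the tie-free shift-DP exact null
_EXACT_DP_N = 40


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    alternative: str
    n1: int
    n2: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


def _check_alternative(alternative: str) -> None:
    if alternative not in _ALTERNATIVES:
        raise ValueError(f"alternative must be one of {_ALTERNATIVES}")


def t_test_two_sample(
    x: Sequence[float], y: Sequence[float], alternative: str = "two-sided"
) -> TestResult:
    """Welch (unequal-variance) two-sample t-test.

    alternative "greater" tests whether x tends larger than y.  When both
    samples are constant and equal, p = 0.5 by convention (with a warning).
    """
    _check_alternative(alternative)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("both samples need n >= 2")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("samples must be finite")
    n1, n2 = len(x), len(y)
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    se2 = vx / n1 + vy / n2
    if se2 == 0.0:
        if x.mean() == y.mean():
            warnings.warn("zero variance in both samples with equal means; p = 0.5")
            return TestResult(0.0, 0.5 if alternative != "two-sided" else 1.0,
                              alternative, n1, n2)
        t_stat = math.inf if x.mean() > y.mean() else -math.inf
        df = float(n1 + n2 - 2)
    else:
        t_stat = float((x.mean() - y.mean()) / math.sqrt(se2))
        df = se2**2 / ((vx / n1) ** 2 / (n1 - 1) + (vy / n2) ** 2 / (n2 - 1))
    if alternative == "greater":
        p = float(_t_dist.sf(t_stat, df))
    elif alternative == "less":
        p = float(_t_dist.cdf(t_stat, df))
    else:
        p = float(2.0 * _t_dist.sf(abs(t_stat), df))
    return TestResult(t_stat, min(1.0, p), alternative, n1, n2)


def _exact_enum_pvalues(ranks: np.ndarray, n1: int, w: float) -> tuple[float, float]:
    """P(W >= w) and P(W <= w) by enumerating all n1-subsets of the midranks."""
    total = ge = le = 0
    for comb in combinations(range(len(ranks)), n1):
        s = float(ranks[list(comb)].sum())
        total += 1
        if s >= w - 1e-9:
            ge += 1
        if s <= w + 1e-9:
            le += 1
    return ge / total, le / total


def _exact_dp_pvalues(n1: int, n2: int, w: int) -> tuple[float, float]:
    """Tie-free exact null of the rank-sum W via subset-sum counting."""
    n = n1 + n2
    max_sum = n1 * (2 * n - n1 + 1) // 2
    # counts[m][s] = number of m-subsets of {1..r} with sum s, built up over r
    counts = np.zeros((n1 + 1, max_sum + 1), dtype=float)
    counts[0, 0] = 1.0
    for r in range(1, n + 1):
        for m in range(min(r, n1), 0, -1):
            counts[m, r:] += counts[m - 1, :-r] if r > 0 else counts[m - 1, :]
    dist = counts[n1]
    total = dist.sum()
    sums = np.arange(max_sum + 1)
    ge = dist[sums >= w].sum() / total
    le = dist[sums <= w].sum() / total
    return float(ge), float(le)


def wilcoxon_rank_sum(
    x: Sequence[float], y: Sequence[float], alternative: str = "two-sided"
) -> TestResult:
    """Wilcoxon rank-sum test; statistic is the rank-sum W of x.

    Exact for small samples (enumeration up to combined n = 20 with ties,
    shift-DP up to 40 without ties), otherwise a normal approximation with
    midranks, tie-corrected variance and continuity correction.
    """
    _check_alternative(alternative)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = len(x), len(y)
    n = n1 + n2
    pooled = np.concatenate([x, y])
    ranks = _rankdata(pooled)  # midranks
    w = float(ranks[:n1].sum())
    has_ties = len(np.unique(pooled)) < n

    if n <= _EXACT_ENUM_N:
        p_ge, p_le = _exact_enum_pvalues(ranks, n1, w)
    elif n <= _EXACT_DP_N and not has_ties:
        p_ge, p_le = _exact_dp_pvalues(n1, n2, int(round(w)))
    else:
        mu = n1 * (n + 1) / 2.0
        _, tie_counts = np.unique(pooled, return_counts=True)
        tie_term = float(((tie_counts**3 - tie_counts).sum()) / ((n) * (n - 1)))
        var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
        if var == 0.0:
            p_ge = p_le = 1.0
        else:
            sd = math.sqrt(var)
            p_ge = float(_norm.sf((w - mu - 0.5) / sd))
            p_le = float(_norm.cdf((w - mu + 0.5) / sd))

    if alternative == "greater":
        p = p_ge
    elif alternative == "less":
        p = p_le
    else:
        p = min(1.0, 2.0 * min(p_ge, p_le))
    return TestResult(w, min(1.0, p), alternative, n1, n2)


def bonferroni(p: float | Iterable[float], m: int):
    """Bonferroni adjustment: min(1, p * m)."""
    if m < 1:
        raise ValueError("m must be >= 1")

    def adjust(v: float) -> float:
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"p-value {v} outside [0, 1]")
        return min(1.0, v * m)

    if isinstance(p, (int, float)):
        return adjust(float(p))
    return [adjust(float(v)) for v in p]
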