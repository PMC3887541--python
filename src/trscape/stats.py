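"""Comparative statistics: Pearson correlation, one-way ANOVA, Tukey HSD.

The arithmetic is implemented directly (sums of squares, studentized-range
quantiles from scipy's distribution); unbalanced designs use the
Tukey-Kramer standard error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .errors import StatsError


@dataclass
class PairwiseComparison:
    group_a: str
    group_b: str
    mean_diff: float
    q_statistic: float
    p_adjusted: float
    significant: bool


@dataclass
class TestResult:
    test: str
    statistic: float
    p_value: float
    df: tuple[float, ...]
    pairwise: list[PairwiseComparison] = field(default_factory=list)


def pearson(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Sample Pearson r with a two-sided p from the t distribution
    (t = r * sqrt((n-2) / (1-r^2)), n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise StatsError("pearson requires two equal-length vectors")
    n = x.size
    if n < 3:
        raise StatsError("pearson requires n >= 3")
    xd = x - x.mean()
    yd = y - y.mean()
    sx = float(np.sqrt((xd * xd).sum()))
    sy = float(np.sqrt((yd * yd).sum()))
    if sx == 0.0 or sy == 0.0:
        raise StatsError("correlation undefined for a constant vector")
    r = float((xd * yd).sum() / (sx * sy))
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * math.sqrt((n - 2) / (1.0 - r * r))
        p = 2.0 * float(sps.t.sf(abs(t), n - 2))
    return TestResult("pearson", r, p, (float(n - 2),))


def _group_arrays(groups: Mapping[str, Sequence[float]]) -> dict[str, np.ndarray]:
    out = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    if len(out) < 2:
        raise StatsError("need at least two groups")
    if any(a.size < 1 for a in out.values()):
        raise StatsError("empty group")
    return out


def _sums_of_squares(arrays: dict[str, np.ndarray]):
    all_vals = np.concatenate(list(arrays.values()))
    grand = all_vals.mean()
    ss_between = sum(a.size * (a.mean() - grand) ** 2 for a in arrays.values())
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays.values())
    k = len(arrays)
    n = all_vals.size
    return float(ss_between), float(ss_within), k, n


def anova_oneway(groups: Mapping[str, Sequence[float]]) -> TestResult:
    """One-way fixed-effects ANOVA: F = MS_between / MS_within."""
    arrays = _group_arrays(groups)
    ssb, ssw, k, n = _sums_of_squares(arrays)
    if n <= k:
        raise StatsError("total n must exceed the number of groups")
    df1, df2 = k - 1, n - k
    msw = ssw / df2
    if msw == 0.0:
        if ssb == 0.0:
            raise StatsError("degenerate data: zero variance everywhere")
        return TestResult("anova", math.inf, 0.0, (float(df1), float(df2)))
    f = (ssb / df1) / msw
    p = float(sps.f.sf(f, df1, df2))
    return TestResult("anova", f, p, (float(df1), float(df2)))


def tukey_hsd(groups: Mapping[str, Sequence[float]], alpha: float = 0.05) -> TestResult:
    """All-pairs Tukey HSD (Tukey-Kramer for unbalanced groups).

    q_ij = |mean_i - mean_j| / sqrt(MS_within / 2 * (1/n_i + 1/n_j)),
    adjusted p from the studentized range with (k, n - k) parameters.
    The scalar statistic/p reported is the largest q (smallest p).
    """
    if not 0.0 < alpha < 1.0:
        raise StatsError("alpha must be in (0, 1)")
    arrays = _group_arrays(groups)
    if any(a.size < 2 for a in arrays.values()):
        raise StatsError("Tukey HSD needs n >= 2 in every group")
    ssb, ssw, k, n = _sums_of_squares(arrays)
    df2 = n - k
    msw = ssw / df2
    if msw == 0.0:
        raise StatsError("zero within-group variance")
    pairs: list[PairwiseComparison] = []
    names = list(arrays)
    for i in range(k):
        for j in range(i + 1, k):
            a, b = arrays[names[i]], arrays[names[j]]
            diff = float(a.mean() - b.mean())
            se = math.sqrt(msw / 2.0 * (1.0 / a.size + 1.0 / b.size))
            q = abs(diff) / se
            p = float(sps.studentized_range.sf(q, k, df2))
            p = min(1.0, max(0.0, p))
            pairs.append(
                PairwiseComparison(names[i], names[j], diff, q, p, p < alpha)
            )
    top = max(pairs, key=lambda c: c.q_statistic)
    return TestResult("tukey_hsd", top.q_statistic, top.p_adjusted, (float(k), float(df2)), pairs)
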