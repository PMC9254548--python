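"""Longitudinal statistics: run-indexed trend tests, first-vs-last-15
group comparisons, and per-section race-time comparisons.

Trends are Pearson correlations of a metric against run index with
two-sided significance from the Student-t transform
t = r sqrt((n-2)/(1-r^2)), evaluated per training period.  Group
comparisons use the Kruskal-Wallis omnibus test (tie-corrected) followed by
Tukey-Kramer pairwise comparisons on rank means with the studentized-range
approximation.  Section crossing times are compared with unpaired two-sided
Wilcoxon rank-sum tests.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sst

__all__ = ["TrendResult", "pearson_trend", "GroupComparison",
           "first_last_comparison", "section_time_comparison",
           "rank_tukey_kramer"]


@dataclass
class TrendResult:
    r: float
    p: float
    n: int
    slope: float
    intercept: float
    degenerate: bool = False

    def __post_init__(self) -> None:
        if self.n < 3:
            raise ValueError("trend needs n >= 3")


def pearson_trend(x: np.ndarray, y: np.ndarray) -> TrendResult:
    """Pearson r of y against x with two-sided t-distribution p-value.

    A zero-variance series is reported as r = 0, p = 1 with the degenerate
    flag set, so batch reports never abort on constant metrics.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    n = x.size
    if n < 3:
        raise ValueError("trend needs n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        return TrendResult(0.0, 1.0, n, 0.0, float(np.mean(y)), True)
    res = sst.pearsonr(x, y)
    fit = sst.linregress(x, y)
    return TrendResult(float(res.statistic), float(res.pvalue), n,
                       float(fit.slope), float(fit.intercept))


@dataclass
class GroupComparison:
    groups: list[str]
    sizes: dict[str, int]
    h_statistic: float
    p_omnibus: float
    pairwise_p: pd.DataFrame | None = None
    posthoc_run: bool = False
    notes: str = ""


def rank_tukey_kramer(samples: dict[str, np.ndarray]) -> pd.DataFrame:
    """Tukey-Kramer pairwise comparisons on rank means.

    All observations are pooled and ranked (midranks for ties); the
    comparison statistic for groups i, j is
    q = |R_i - R_j| / sqrt(S^2/2 (1/n_i + 1/n_j)) referred to the
    studentized range distribution with k groups and infinite degrees of
    freedom, where S^2 is the (tie-adjusted) variance of the pooled ranks.
    """
    names = list(samples)
    pooled = np.concatenate([np.asarray(samples[g], dtype=float)
                             for g in names])
    ranks = sst.rankdata(pooled)
    splits = np.cumsum([len(samples[g]) for g in names])[:-1]
    by_group = dict(zip(names, np.split(ranks, splits)))
    s2 = float(np.var(ranks, ddof=1))
    k = len(names)
    out = pd.DataFrame(np.ones((k, k)), index=names, columns=names)
    for a, b in itertools.combinations(names, 2):
        ra, rb = by_group[a].mean(), by_group[b].mean()
        na, nb = len(by_group[a]), len(by_group[b])
        se = np.sqrt(s2 / 2.0 * (1.0 / na + 1.0 / nb))
        if se == 0:
            p = 1.0
        else:
            q = abs(ra - rb) / se
            p = float(sst.studentized_range.sf(q, k, 1e7))
        out.loc[a, b] = out.loc[b, a] = min(1.0, p)
    return out


def first_last_comparison(samples: dict[str, np.ndarray],
                          alpha: float = 0.05) -> GroupComparison:
    """Kruskal-Wallis omnibus over the groups, Tukey-Kramer post hoc.

    Typical groups are the metric values of the first and last 15 runs of
    each training period.  Post-hoc pairwise comparisons are attached when
    the omnibus p is below ``alpha``.  All-identical data yields H = 0,
    p = 1 and no post hoc.
    """
    names = list(samples)
    if len(names) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [np.asarray(samples[g], dtype=float) for g in names]
    if any(a.size < 2 for a in arrays):
        raise ValueError("each group needs at least 2 values")
    sizes = {g: int(a.size) for g, a in zip(names, arrays)}
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return GroupComparison(names, sizes, 0.0, 1.0, None, False,
                               "all observations identical")
    h, p = sst.kruskal(*arrays)
    comp = GroupComparison(names, sizes, float(h), float(p))
    if p < alpha:
        comp.pairwise_p = rank_tukey_kramer(dict(zip(names, arrays)))
        comp.posthoc_run = True
    return comp


def section_time_comparison(first: dict[str, np.ndarray],
                            last: dict[str, np.ndarray]) -> pd.DataFrame:
    """Unpaired two-sided Wilcoxon rank-sum test per section type.

    Returns a DataFrame indexed by section type with the statistic, the
    p-value and the two sample sizes.  Degenerate samples (all values
    identical across both groups) report p = 1 with a flag.
    """
    rows = []
    for sec in first:
        a = np.asarray(first[sec], dtype=float)
        b = np.asarray(last.get(sec, []), dtype=float)
        if a.size == 0 or b.size == 0:
            raise ValueError(f"empty sample for section {sec!r}")
        pooled = np.concatenate([a, b])
        if np.all(pooled == pooled[0]):
            rows.append((sec, 0.0, 1.0, a.size, b.size, True))
            continue
        stat, p = sst.ranksums(a, b)
        rows.append((sec, float(stat), float(p), a.size, b.size, False))
    return pd.DataFrame(rows, columns=["section", "statistic", "p",
                                       "n_first", "n_last", "degenerate"]
                        ).set_index("section")
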