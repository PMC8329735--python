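"""Group-level inference: one-way ANOVA with η², Tukey HSD post-hoc
comparisons, and simple linear regression of CP metrics on age.

The ANOVA uses the classical sum-of-squares decomposition
``SS_total = SS_between + SS_within`` with ``η² = SS_between/SS_total``.
Pairwise comparisons use the studentized-range (Tukey HSD) adjustment,
with the Tukey–Kramer standard error for unbalanced groups.  No
correction is applied across the family of ANOVAs.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GroupComparisonResult",
    "RegressionResult",
    "one_way_anova",
    "tukey_hsd",
    "simple_regression",
]


@dataclass(frozen=True)
class PairwiseComparison:
    group_a: str
    group_b: str
    mean_diff: float  # mean(a) − mean(b)
    adjusted_p: float


@dataclass(frozen=True)
class GroupComparisonResult:
    F: float
    df_between: int
    df_within: int
    p: float
    eta_sq: float
    group_means: dict[str, float]
    group_ns: dict[str, int]
    pairwise: tuple[PairwiseComparison, ...]


@dataclass(frozen=True)
class RegressionResult:
    beta0: float
    beta1: float
    r_sq: float
    F: float
    p: float
    n: int


def _validate_groups(values_by_group: Mapping[str, Sequence[float]]):
    if len(values_by_group) < 2:
        raise ValueError("need at least 2 groups")
    groups = {}
    for g in values_by_group:
        arr = np.asarray(values_by_group[g], dtype=float)
        arr = arr[np.isfinite(arr)]
        if len(arr) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 finite observations")
        groups[str(g)] = arr
    return groups


def tukey_hsd(
    values_by_group: Mapping[str, Sequence[float]]
) -> tuple[PairwiseComparison, ...]:
    """All k(k−1)/2 pairwise comparisons with studentized-range adjusted
    p-values (Tukey–Kramer for unequal group sizes)."""
    groups = _validate_groups(values_by_group)
    names = sorted(groups)
    res = stats.tukey_hsd(*(groups[g] for g in names))
    out = []
    for i, j in combinations(range(len(names)), 2):
        out.append(
            PairwiseComparison(
                group_a=names[i],
                group_b=names[j],
                mean_diff=float(groups[names[i]].mean() - groups[names[j]].mean()),
                adjusted_p=float(res.pvalue[i, j]),
            )
        )
    return tuple(out)


def one_way_anova(
    values_by_group: Mapping[str, Sequence[float]], with_pairwise: bool = True
) -> GroupComparisonResult:
    """Fixed-effects one-way ANOVA with effect size η²; optionally runs
    Tukey HSD pairwise comparisons on the same data."""
    groups = _validate_groups(values_by_group)
    names = sorted(groups)
    allv = np.concatenate([groups[g] for g in names])
    grand = allv.mean()
    ss_total = float(np.sum((allv - grand) ** 2))
    ss_between = float(
        sum(len(groups[g]) * (groups[g].mean() - grand) ** 2 for g in names)
    )
    ss_within = float(sum(np.sum((groups[g] - groups[g].mean()) ** 2) for g in names))
    k = len(names)
    N = len(allv)
    df_b, df_w = k - 1, N - k
    ms_b = ss_between / df_b
    ms_w = ss_within / df_w
    if ms_w == 0:
        F = float("inf") if ms_b > 0 else 0.0
    else:
        F = ms_b / ms_w
    p = float(stats.f.sf(F, df_b, df_w)) if np.isfinite(F) else 0.0
    eta_sq = ss_between / ss_total if ss_total > 0 else 0.0
    return GroupComparisonResult(
        F=float(F),
        df_between=df_b,
        df_within=df_w,
        p=p,
        eta_sq=float(eta_sq),
        group_means={g: float(groups[g].mean()) for g in names},
        group_ns={g: len(groups[g]) for g in names},
        pairwise=tukey_hsd(values_by_group) if with_pairwise else (),
    )


def simple_regression(x: Sequence[float], y: Sequence[float]) -> RegressionResult:
    """Ordinary least-squares regression of a metric on one predictor
    (typically chronological age in decimal years).

    Reports slope, intercept, r², and the model F-test, which for simple
    regression satisfies F = (r²/(1 − r²))·(n − 2).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0:
        raise ValueError("predictor is constant")
    xc = x - x.mean()
    yc = y - y.mean()
    beta1 = float(np.sum(xc * yc) / np.sum(xc**2))
    beta0 = float(y.mean() - beta1 * x.mean())
    ss_tot = float(np.sum(yc**2))
    resid = y - (beta0 + beta1 * x)
    ss_res = float(np.sum(resid**2))
    r_sq = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    if r_sq >= 1.0:
        F = float("inf")
        p = 0.0
    else:
        F = (r_sq / (1.0 - r_sq)) * (n - 2)
        p = float(stats.f.sf(F, 1, n - 2))
    return RegressionResult(beta0=beta0, beta1=beta1, r_sq=float(r_sq), F=float(F), p=p, n=n)


def anova_table(results: Mapping[str, GroupComparisonResult]) -> pd.DataFrame:
    """Flatten a set of named ANOVA results into one tidy frame."""
    rows = []
    for metric, r in results.items():
        rows.append(
            {
                "metric": metric,
                "F": r.F,
                "df_between": r.df_between,
                "df_within": r.df_within,
                "p": r.p,
                "eta_sq": r.eta_sq,
            }
        )
    return pd.DataFrame(rows)


def pairwise_table(results: Mapping[str, GroupComparisonResult]) -> pd.DataFrame:
    rows = []
    for metric, r in results.items():
        for c in r.pairwise:
            rows.append(
                {
                    "metric": metric,
                    "group_a": c.group_a,
                    "group_b": c.group_b,
                    "mean_diff": c.mean_diff,
                    "adjusted_p": c.adjusted_p,
                }
            )
    return pd.DataFrame(rows)
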