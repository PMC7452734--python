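"""Condition-comparison statistics: mean +/- SEM, Student's t, ANOVA + Tukey.

Reproduces the comparison workflow used for the per-animal activity and
width metrics: group summaries as mean +/- SEM, two-tailed unpaired
(pooled-variance) Student's t tests for two-group factors, and one-way
ANOVA with Tukey's HSD multiple-comparison test (Tukey-Kramer correction
for unequal n) with simultaneous 95% CIs of the pairwise differences for
the three osmolarity levels.  Significance is always derived from
p < alpha, and for Tukey rows coincides with 0 lying outside the CI.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from ._studentized_range import sr_ppf, sr_sf

__all__ = [
    "GroupData",
    "ComparisonRow",
    "TTestResult",
    "AnovaTukeyResult",
    "group_summary",
    "t_test_unpaired",
    "one_way_anova",
    "anova_tukey",
    "build_report",
    "REPORT_COLUMNS",
]

REPORT_COLUMNS = ["Figure", "Description", "Method", "CI_low", "CI_high",
                  "Significant", "p"]


@dataclass
class GroupData:
    """Per-animal values of one metric under one condition."""

    label: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size < 2:
            raise ValueError(f"group {self.label!r} needs n >= 2")
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"group {self.label!r} has non-finite values")

    @property
    def n(self) -> int:
        return self.values.size


@dataclass
class ComparisonRow:
    """One pairwise comparison (one row of the report table)."""

    description: str
    method: str              # "t_test" or "anova_tukey"
    ci_low: float
    ci_high: float
    significant: bool
    p_value: float

    def __post_init__(self) -> None:
        if self.ci_low > self.ci_high:
            raise ValueError("ci_low must be <= ci_high")


@dataclass
class TTestResult:
    t: float
    df: int
    p: float


@dataclass
class AnovaTukeyResult:
    f: float
    p: float
    rows: list[ComparisonRow]


def group_summary(group: GroupData) -> tuple[float, float, int]:
    """(mean, SEM, n) with the n-1 sample SD."""
    sd = float(np.std(group.values, ddof=1))
    return float(np.mean(group.values)), sd / math.sqrt(group.n), group.n


def t_test_unpaired(a: GroupData, b: GroupData) -> TTestResult:
    """Two-tailed unpaired Student's t test (pooled variance).

    Degenerate zero-variance data uses the documented convention:
    p = 1 when the means are equal, p = 0 otherwise.
    """
    na, nb = a.n, b.n
    df = na + nb - 2
    ma, mb = float(np.mean(a.values)), float(np.mean(b.values))
    ssa = float(np.sum((a.values - ma) ** 2))
    ssb = float(np.sum((b.values - mb) ** 2))
    pooled = (ssa + ssb) / df
    if pooled == 0.0:
        if ma == mb:
            return TTestResult(0.0, df, 1.0)
        return TTestResult(math.copysign(math.inf, ma - mb), df, 0.0)
    t = (ma - mb) / math.sqrt(pooled * (1.0 / na + 1.0 / nb))
    p = 2.0 * sps.t.sf(abs(t), df)
    return TTestResult(t, df, min(p, 1.0))


def _t_comparison_row(a: GroupData, b: GroupData, alpha: float,
                      description: str) -> ComparisonRow:
    res = t_test_unpaired(a, b)
    diff = float(np.mean(a.values) - np.mean(b.values))
    ma, mb = float(np.mean(a.values)), float(np.mean(b.values))
    pooled = (np.sum((a.values - ma) ** 2) + np.sum((b.values - mb) ** 2)) / res.df
    se = math.sqrt(pooled * (1.0 / a.n + 1.0 / b.n))
    tcrit = float(sps.t.ppf(1.0 - alpha / 2.0, res.df))
    return ComparisonRow(
        description=description,
        method="t_test",
        ci_low=diff - tcrit * se,
        ci_high=diff + tcrit * se,
        significant=res.p < alpha,
        p_value=res.p,
    )


def one_way_anova(groups: Sequence[GroupData]) -> tuple[float, float, float, int]:
    """One-way fixed-effects ANOVA: (F, p, MS_within, df_within).

    Valid for two or more groups; with two groups F equals the squared
    pooled t statistic.
    """
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    k = len(groups)
    ns = np.array([g.n for g in groups])
    means = np.array([float(np.mean(g.values)) for g in groups])
    n_total = int(ns.sum())
    df_within = n_total - k
    grand = float(np.concatenate([g.values for g in groups]).mean())
    ss_between = float(np.sum(ns * (means - grand) ** 2))
    ss_within = float(sum(np.sum((g.values - m) ** 2)
                          for g, m in zip(groups, means)))
    ms_between = ss_between / (k - 1)
    ms_within = ss_within / df_within
    if ms_within == 0.0:
        f = math.inf if ms_between > 0 else 0.0
        p = 0.0 if ms_between > 0 else 1.0
    else:
        f = ms_between / ms_within
        p = float(sps.f.sf(f, k - 1, df_within))
    return f, p, ms_within, df_within


def anova_tukey(groups: Sequence[GroupData], alpha: float = 0.05) -> AnovaTukeyResult:
    """One-way fixed-effects ANOVA with Tukey HSD pairwise comparisons.

    Pairwise rows follow the input group order ((0,1), (0,2), (1,2), ...),
    so passing (control, low, high) yields control-vs-low,
    control-vs-high, low-vs-high.  CIs use the studentized-range critical
    value with the Tukey-Kramer unequal-n standard error; p-values come
    from the studentized-range survival function, so significance,
    p < alpha, and 0 outside the CI all agree.
    """
    if len(groups) < 3:
        raise ValueError("anova_tukey needs >= 3 groups; "
                         "use t_test_unpaired for two")
    k = len(groups)
    ns = np.array([g.n for g in groups])
    means = np.array([float(np.mean(g.values)) for g in groups])
    f, p_f, ms_within, df_within = one_way_anova(groups)
    q_crit = sr_ppf(1.0 - alpha, k, float(df_within))
    rows = []
    for i, j in itertools.combinations(range(k), 2):
        diff = means[i] - means[j]
        se = math.sqrt(ms_within / 2.0 * (1.0 / ns[i] + 1.0 / ns[j]))
        if se == 0.0:
            p = 1.0 if diff == 0 else 0.0
            half = 0.0
        else:
            q = abs(diff) / se
            p = float(sr_sf(q, k, float(df_within)))
            half = q_crit * se
        rows.append(ComparisonRow(
            description=f"{groups[i].label} vs {groups[j].label}",
            method="anova_tukey",
            ci_low=diff - half,
            ci_high=diff + half,
            significant=p < alpha,
            p_value=p,
        ))
    return AnovaTukeyResult(f=f, p=p_f, rows=rows)


def build_report(
    metric_tables: Mapping[str, Mapping[str, Sequence[GroupData]]],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Build the comparison table: one row per pairwise comparison.

    ``metric_tables`` maps metric name -> factor name -> ordered groups.
    Factors with two groups get a t-test row; three or more get the
    ANOVA + Tukey rows.
    """
    records = []
    for metric, factors in metric_tables.items():
        for factor, groups in factors.items():
            groups = list(groups)
            if len(groups) < 2:
                raise ValueError(f"factor {factor!r} needs >= 2 groups")
            if len(groups) == 2:
                rows = [_t_comparison_row(
                    groups[0], groups[1], alpha,
                    f"{factor}: {groups[0].label} vs {groups[1].label}")]
            else:
                result = anova_tukey(groups, alpha)
                rows = [ComparisonRow(f"{factor}: {r.description}", r.method,
                                      r.ci_low, r.ci_high, r.significant,
                                      r.p_value)
                        for r in result.rows]
            for r in rows:
                records.append({
                    "Figure": metric,
                    "Description": r.description,
                    "Method": r.method,
                    "CI_low": r.ci_low,
                    "CI_high": r.ci_high,
                    "Significant": r.significant,
                    "p": r.p_value,
                })
    return pd.DataFrame.from_records(records, columns=REPORT_COLUMNS)
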