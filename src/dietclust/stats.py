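"""Descriptive group comparisons: t-test, chi-square, one-way ANOVA,
incidence proportions and table-style summaries.

Conventions: continuous variables are reported as mean +/- SD and compared by
a pooled-variance (Student) independent-samples t-test or one-way ANOVA;
categoricals as counts (%) compared by the Pearson chi-square test without
continuity correction.  Percentages are rounded to 1 decimal, statistics to
2, p-values to 3 — no multiple-testing correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ttest_independent",
    "chi_square_test",
    "anova_oneway",
    "incidence_proportion",
    "GroupSummary",
    "summarize_continuous",
    "summarize_categorical",
]


def ttest_independent(
    x, y, equal_var: bool = True
) -> tuple[float, float]:
    """Two-sided independent-samples t-test (pooled variance by default;
    set ``equal_var=False`` for Welch)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each sample must have >= 2 observations")
    if np.var(x) == 0 and np.var(y) == 0 and np.mean(x) == np.mean(y):
        return 0.0, 1.0
    t, p = sps.ttest_ind(x, y, equal_var=equal_var)
    return float(t), float(p)


def chi_square_test(table) -> tuple[float, int, float]:
    """Pearson chi-square test of independence on an r x c count table.

    No continuity correction; expected counts from the margins;
    df = (r-1)(c-1).  Zero row or column margins are rejected.
    """
    obs = np.asarray(table, float)
    if obs.ndim != 2 or np.any(obs < 0) or obs.sum() <= 0:
        raise ValueError("table must be a nonnegative 2-D count matrix with total > 0")
    if np.any(obs.sum(axis=0) == 0) or np.any(obs.sum(axis=1) == 0):
        raise ValueError("zero row or column margin")
    res = sps.chi2_contingency(obs, correction=False)
    return float(res.statistic), int(res.dof), float(res.pvalue)


def anova_oneway(groups) -> tuple[float, int, int, float]:
    """One-way fixed-effects ANOVA: returns (F, df_between, df_within, p)."""
    arrays = [np.asarray(g, float) for g in groups]
    if len(arrays) < 2 or any(len(g) < 2 for g in arrays):
        raise ValueError("need >= 2 groups with >= 2 observations each")
    all_vals = np.concatenate(arrays)
    df1 = len(arrays) - 1
    df2 = len(all_vals) - len(arrays)
    if np.ptp(all_vals) == 0:
        return 0.0, df1, df2, 1.0
    f, p = sps.f_oneway(*arrays)
    return float(f), df1, df2, float(p)


def incidence_proportion(cases: int, total: int) -> float:
    """100 * cases / total, half-up rounded to 1 decimal."""
    if total <= 0:
        raise ValueError("total must be > 0")
    if not 0 <= cases <= total:
        raise ValueError("cases must lie in [0, total]")
    pct = Decimal(100 * cases) / Decimal(total)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass
class GroupSummary:
    """One table row: per-group description plus the comparison test."""

    variable: str
    kind: str                      # "continuous" | "categorical"
    groups: dict                   # group -> (mean, sd) or {level: (count, pct)}
    statistic: float
    p_value: float
    test: str

    def rounded(self) -> "GroupSummary":
        return GroupSummary(
            self.variable,
            self.kind,
            self.groups,
            round(self.statistic, 2),
            round(self.p_value, 3),
            self.test,
        )


def summarize_continuous(
    data: pd.DataFrame, variable: str, by: str
) -> GroupSummary:
    """Mean +/- SD per group; two groups -> pooled t-test, more -> ANOVA."""
    grouped = [
        (key, sub[variable].to_numpy(float)) for key, sub in data.groupby(by, sort=True)
    ]
    desc = {k: (float(np.mean(v)), float(np.std(v, ddof=1))) for k, v in grouped}
    samples = [v for _, v in grouped]
    if len(samples) == 2:
        stat, p = ttest_independent(*samples)
        test = "t-test"
    else:
        stat, _, _, p = anova_oneway(samples)
        test = "anova"
    return GroupSummary(variable, "continuous", desc, stat, p, test)


def summarize_categorical(
    data: pd.DataFrame, variable: str, by: str
) -> GroupSummary:
    """Counts (%) per group and level; Pearson chi-square comparison."""
    table = pd.crosstab(data[variable], data[by])
    stat, _, p = chi_square_test(table.to_numpy())
    desc = {}
    for g in table.columns:
        col = table[g]
        total = int(col.sum())
        desc[g] = {
            str(lev): (int(col[lev]), incidence_proportion(int(col[lev]), total))
            for lev in table.index
        }
    return GroupSummary(variable, "categorical", desc, stat, p, "chi-square")
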