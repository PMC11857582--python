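"""Zygosity-group descriptive comparisons with normality-based test routing.

Continuous variables are Shapiro-Wilk tested per zygosity group: if both
groups look normal at the chosen alpha the groups are compared with an
independent-samples t-test and summarized as mean +/- SD; otherwise a
Mann-Whitney U test is used with median +/- IQR (reported as Q3 - Q1).
Categorical variables go to a chi-squared test on the contingency table with
counts and percentages.  Subjects, not pairs, are the unit of comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateDataError, ValidationError
from .io import CohortTable

__all__ = ["GroupComparison", "compare_groups", "descriptives_table"]


@dataclass(frozen=True)
class GroupComparison:
    variable: str
    test_used: str  # t_test | mann_whitney | chi_squared
    statistic: float
    p_value: float
    group_summaries: dict[str, Any] = field(default_factory=dict)


def _summary_continuous(x: np.ndarray, parametric: bool) -> dict[str, float]:
    if parametric:
        return {"mean": float(np.mean(x)), "sd": float(np.std(x, ddof=1)), "n": int(x.size)}
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    return {"median": float(med), "iqr": float(q3 - q1), "n": int(x.size)}


def compare_groups(
    cohort: CohortTable,
    variable: str,
    kind: str = "continuous",
    alpha: float = 0.05,
    *,
    continuity_correction: bool = False,
) -> GroupComparison:
    """Compare one variable between MZ and DZ subjects with routed testing.

    Routing is deterministic given the data: each zygosity group is
    Shapiro-Wilk tested and the nonparametric route is taken if *either*
    group rejects normality at ``alpha``.
    """
    df = cohort.df
    if variable not in df.columns:
        raise KeyError(f"unknown variable {variable!r}")
    if kind not in ("continuous", "categorical"):
        raise ValidationError(f"kind must be continuous or categorical, got {kind!r}")

    groups = {z: df.loc[df["zygosity"] == z, variable].dropna() for z in ("MZ", "DZ")}
    if any(g.empty for g in groups.values()):
        raise ValidationError("both zygosity groups must be nonempty")

    if kind == "categorical":
        table = pd.crosstab(df["zygosity"], df[variable])
        if (table.sum(axis=1) == 0).any() or (table.sum(axis=0) == 0).any():
            raise ValidationError("contingency table has an all-zero row or column")
        chi2, p, _, _ = stats.chi2_contingency(table, correction=continuity_correction)
        summaries = {
            z: {str(k): {"count": int(c), "percent": float(100.0 * c / table.loc[z].sum())}
                for k, c in table.loc[z].items()}
            for z in table.index
        }
        return GroupComparison(variable, "chi_squared", float(chi2), float(p), summaries)

    arrs = {z: g.to_numpy(dtype=float) for z, g in groups.items()}
    if any(np.ptp(a) == 0 for a in arrs.values()):
        raise DegenerateDataError(f"variable {variable!r} has zero variance in a group")

    normal = all(stats.shapiro(a).pvalue >= alpha for a in arrs.values())
    if normal:
        res = stats.ttest_ind(arrs["MZ"], arrs["DZ"], equal_var=True)
        test, stat, p = "t_test", float(res.statistic), float(res.pvalue)
    else:
        res = stats.mannwhitneyu(arrs["MZ"], arrs["DZ"], alternative="two-sided")
        test, stat, p = "mann_whitney", float(res.statistic), float(res.pvalue)
    summaries = {z: _summary_continuous(a, parametric=normal) for z, a in arrs.items()}
    return GroupComparison(variable, test, stat, p, summaries)


def descriptives_table(
    cohort: CohortTable,
    variables: dict[str, str] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Run :func:`compare_groups` over a variable->kind map and tabulate.

    Defaults to the covariates present in every cohort table (sex as
    categorical, age as continuous) plus any extra columns named in
    ``variables``.
    """
    if variables is None:
        variables = {"sex": "categorical", "age_years": "continuous"}
    rows = []
    for var, kind in variables.items():
        gc = compare_groups(cohort, var, kind, alpha)
        rows.append(
            {
                "variable": var,
                "test": gc.test_used,
                "statistic": gc.statistic,
                "p_value": gc.p_value,
                "summary": repr(gc.group_summaries),
            }
        )
    return pd.DataFrame(rows)
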