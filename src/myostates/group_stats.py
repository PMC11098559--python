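"""Hierarchical aggregation and group-comparison statistics on animal means.

Per-fiber measurements are never compared directly across conditions: the
animal is the experimental unit, so fibers are first averaged within each
animal x condition x fiber type x temperature stratum and all tests run on
those animal means.  One-way ANOVA compares conditions within a stratum;
two-way ANOVA (type-II sums of squares, with interaction) handles factorial
layouts such as PTM-site x condition z-scores, with Sidak-adjusted pairwise
follow-ups.  No multiplicity correction is applied across the many
stratum x metric one-way ANOVAs, and reports state that explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AnimalSummaryColumns",
    "TestResult",
    "aggregate_by_animal",
    "one_way_anova",
    "sidak_adjust",
    "sidak_pairwise",
    "two_way_anova",
    "significance_stars",
]

DEFAULT_METRICS = ("p1_pct", "p2_pct", "t1_s", "t2_s", "atp_consumption_uM_per_min")
AnimalSummaryColumns = ("animal_id", "condition", "fiber_type", "temperature_C")


@dataclass(frozen=True)
class TestResult:
    """A single hypothesis test: statistic, degrees of freedom, p, stars."""

    name: str
    grouping: str
    statistic: float
    df: tuple
    p_value: float
    p_adjusted: float | None = None
    adjust_method: str | None = None

    @property
    def stars(self) -> str:
        return significance_stars(
            self.p_adjusted if self.p_adjusted is not None else self.p_value
        )


def significance_stars(p: float) -> str:
    """Conventional star notation: * p<0.05, ** p<0.01, *** p<0.001, **** p<0.0001."""
    if p < 1e-4:
        return "****"
    if p < 1e-3:
        return "***"
    if p < 1e-2:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def aggregate_by_animal(
    records: pd.DataFrame,
    metrics=DEFAULT_METRICS,
    by=AnimalSummaryColumns,
) -> pd.DataFrame:
    """Unweighted per-animal means/SDs of fiber metrics, one row per stratum.

    Strata with no accepted fibers simply produce no row.  Duplicating every
    fiber leaves the means unchanged (the mean is unweighted over fibers).
    """
    metrics = [m for m in metrics if m in records.columns]
    by = [b for b in by if b in records.columns]
    g = records.groupby(by, sort=True)[metrics]
    summary = g.agg(["mean", "std", "count"])
    summary.columns = [f"{m}_{stat}" for m, stat in summary.columns]
    summary = summary.reset_index()
    # one shared fiber count per stratum
    counts = [c for c in summary.columns if c.endswith("_count")]
    summary["n_fibers"] = summary[counts[0]].astype(int)
    return summary.drop(columns=counts)


def one_way_anova(groups) -> TestResult:
    """Classical fixed-effects one-way ANOVA on animal-mean vectors.

    ``groups`` is a sequence of 1-D arrays, one per condition, each holding
    the animal means of that condition.  Requires >= 2 groups of >= 2 values.
    """
    groups = [np.asarray(g, float) for g in groups]
    if len(groups) < 2:
        raise ValueError("one-way ANOVA needs at least two groups")
    for i, g in enumerate(groups):
        if g.size < 2:
            raise ValueError(f"group {i} has {g.size} value(s); need >= 2")
    f, p = stats.f_oneway(*groups)
    k = len(groups)
    n = sum(g.size for g in groups)
    return TestResult(
        name="one_way_anova",
        grouping=f"{k} groups",
        statistic=float(f),
        df=(k - 1, n - k),
        p_value=float(p),
    )


def sidak_adjust(p, m: int):
    """Sidak multiplicity adjustment: p' = 1 - (1 - p)^m for a family of m."""
    if m < 1:
        raise ValueError("family size m must be >= 1")
    p = np.asarray(p, float)
    adj = 1.0 - (1.0 - p) ** m
    return adj if adj.shape else float(adj)


def sidak_pairwise(groups: dict, equal_var: bool = True) -> pd.DataFrame:
    """All pairwise t-tests between named groups, Sidak-adjusted as one family.

    ``groups`` maps label -> 1-D array.  Uses pooled-variance t-tests by
    default (``equal_var=False`` for Welch).  Returns one row per comparison
    with raw p, Sidak-adjusted p (m = number of comparisons) and stars.
    """
    labels = list(groups)
    if len(labels) < 2:
        raise ValueError("need at least two groups for pairwise comparisons")
    pairs = [(a, b) for i, a in enumerate(labels) for b in labels[i + 1 :]]
    rows = []
    for a, b in pairs:
        t, p = stats.ttest_ind(groups[a], groups[b], equal_var=equal_var)
        rows.append({"group_a": a, "group_b": b, "t": float(t), "p_raw": float(p)})
    out = pd.DataFrame(rows)
    out["p_sidak"] = sidak_adjust(out["p_raw"].to_numpy(), len(pairs))
    out["stars"] = out["p_sidak"].map(significance_stars)
    return out


def two_way_anova(
    data: pd.DataFrame,
    value: str,
    factor_a: str,
    factor_b: str,
    interaction: bool = True,
) -> pd.DataFrame:
    """Fixed-effects two-way ANOVA with type-II sums of squares.

    Type II is the standard choice for mildly unbalanced layouts.  Returns
    one row per term (factors and, optionally, their interaction) with F,
    degrees of freedom, p and stars.  Each factor needs >= 2 levels.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    for f in (factor_a, factor_b):
        if data[f].nunique() < 2:
            raise ValueError(f"factor {f!r} has fewer than two levels")
    d = data[[value, factor_a, factor_b]].rename(
        columns={value: "y", factor_a: "fa", factor_b: "fb"}
    )
    if np.ptp(d["y"].to_numpy(float)) == 0:
        # degenerate all-constant response: every effect is exactly zero
        terms = [factor_a, factor_b] + ([f"{factor_a}:{factor_b}"] if interaction else [])
        return pd.DataFrame(
            {"term": terms, "F": 0.0, "df": [()] * len(terms), "p_value": 1.0,
             "stars": "ns"}
        )
    formula = "y ~ C(fa) + C(fb)" + (" + C(fa):C(fb)" if interaction else "")
    fit = smf.ols(formula, data=d).fit()
    table = sm.stats.anova_lm(fit, typ=2)
    resid_df = float(table.loc["Residual", "df"])
    rows = []
    rename = {"C(fa)": factor_a, "C(fb)": factor_b, "C(fa):C(fb)": f"{factor_a}:{factor_b}"}
    for term, row in table.iterrows():
        if term == "Residual":
            continue
        # all-constant data: statsmodels reports NaN F; a zero effect is F=0
        f_val = 0.0 if np.isnan(row["F"]) else float(row["F"])
        p_val = 1.0 if np.isnan(row["PR(>F)"]) else float(row["PR(>F)"])
        rows.append(
            {
                "term": rename.get(term, term),
                "F": f_val,
                "df": (float(row["df"]), resid_df),
                "p_value": p_val,
                "stars": significance_stars(p_val),
            }
        )
    return pd.DataFrame(rows)
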