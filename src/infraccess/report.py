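"""Summary reporting: group statistics, North/South ratios, model tables.

Includes the published country-group mean access and inequality values from
the global-scale study this pipeline mirrors; they are treated purely as
reference inputs for ratio cross-checks, never as computed output.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from infraccess.health import group_comparisons

__all__ = [
    "REFERENCE_GROUP_MEANS",
    "group_ratio",
    "north_south_ratios",
    "group_stats_table",
    "model_summary_table",
]

#: Published country-group means (access and Gini by category) reported by
#: the global analysis: rows are groups, columns ``access_*`` / ``gini_*``.
REFERENCE_GROUP_MEANS = pd.DataFrame(
    {
        "access_economic": [0.45, 0.36],
        "access_social": [0.44, 0.22],
        "access_environmental": [0.43, 0.30],
        "gini_economic": [0.47, 0.58],
        "gini_social": [0.78, 0.85],
        "gini_environmental": [0.27, 0.39],
    },
    index=pd.Index(["North", "South"], name="group"),
)


def group_ratio(means: pd.DataFrame, numerator: str, denominator: str, ndigits: int = 2) -> pd.Series:
    """Row-ratio of a group-means table, rounded.

    ``means`` is indexed by group with one column per quantity; the result
    is ``means.loc[numerator] / means.loc[denominator]`` rounded to
    ``ndigits`` (the convention used when quoting, e.g., "access in the
    North is 1.25 times the South's").
    """
    for g in (numerator, denominator):
        if g not in means.index:
            raise KeyError(f"group {g!r} not in means table")
    denom = means.loc[denominator]
    if (denom == 0).any():
        raise ZeroDivisionError("denominator group has a zero mean")
    return (means.loc[numerator] / denom).round(ndigits)


def north_south_ratios(means: pd.DataFrame | None = None, ndigits: int = 2) -> pd.Series:
    """North/South access ratios and South/North inequality ratios.

    Access is higher in the North, inequality higher in the South, so each
    family is quoted with the larger group in the numerator.  Defaults to
    the published reference means.
    """
    if means is None:
        means = REFERENCE_GROUP_MEANS
    access_cols = [c for c in means.columns if c.startswith("access_")]
    gini_cols = [c for c in means.columns if c.startswith("gini_")]
    out = {}
    if access_cols:
        out.update(group_ratio(means[access_cols], "North", "South", ndigits).to_dict())
    if gini_cols:
        out.update(group_ratio(means[gini_cols], "South", "North", ndigits).to_dict())
    return pd.Series(out)


def group_stats_table(
    data: pd.DataFrame,
    value_cols: list[str],
    group_col: str = "group",
    region_col: str | None = "region",
) -> pd.DataFrame:
    """Per-quantity group means ± sd with t-test (two groups) and region ANOVA.

    One row per value column and comparison, mirroring the layout of a
    group-statistics summary table: group means, sds, the test statistic,
    p-value and effect size.
    """
    rows = []
    for col in value_cols:
        t_row = group_comparisons(data, col, group_col).iloc[0].to_dict()
        t_row.update({"quantity": col, "comparison": f"{group_col}"})
        rows.append(t_row)
        if region_col is not None and data[region_col].nunique() > 2:
            a_row = group_comparisons(data, col, region_col).iloc[0].to_dict()
            a_row.update({"quantity": col, "comparison": f"{region_col}"})
            rows.append(a_row)
    out = pd.DataFrame(rows)
    front = ["quantity", "comparison", "test", "statistic", "p", "effect_name", "effect_size"]
    rest = [c for c in out.columns if c not in front]
    return out[front + rest]


def model_summary_table(results: list) -> pd.DataFrame:
    """Stack fixed-effect summaries of several fitted models into one table."""
    frames = []
    for res in results:
        frame = res.summary.copy()
        frame.insert(0, "model_id", res.model_id)
        frame["r2"] = res.r2
        frame["robust_se_used"] = res.robust_se_used
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)


def computed_group_means(access: pd.DataFrame, inequality: pd.DataFrame, units: pd.DataFrame) -> pd.DataFrame:
    """Group-means table (same layout as the reference table) from pipeline outputs."""
    acc = access.merge(units[["unit_id", "group"]], on="unit_id")
    acc_means = (
        acc.pivot_table(index="group", columns="category", values="ie_norm", aggfunc="mean")
        .rename(columns=lambda c: f"access_{c}")
    )
    ine = inequality.merge(units[["unit_id", "group"]], on="unit_id")
    gini_means = (
        ine.pivot_table(index="group", columns="category", values="gini", aggfunc="mean")
        .rename(columns=lambda c: f"gini_{c}")
    )
    out = acc_means.join(gini_means)
    out.columns.name = None
    return out
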