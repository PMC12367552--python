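"""Composite high/medium/low classification of access values.

Per dimension (economic, social, environmental), units below the 25th
percentile are Low, above the 75th High, and Medium otherwise; values
exactly on a threshold are Medium.  The three letters are joined into one
of 27 categories ("H-M-L" means high economic, medium social, low
environmental access) and every category maps to exactly one general class:

* Class I   — no dimension Low (access at or above average across the board)
* Class II  — at least one High and at least one Low (strong disparity)
* Class III — no dimension High (uniformly below-average access)
"""

from __future__ import annotations

import itertools
import warnings

import numpy as np
import pandas as pd

__all__ = [
    "LEVELS",
    "ALL_CATEGORIES",
    "classify_dimension",
    "composite_category",
    "assign_class",
    "classify_units",
]

LEVELS = ("H", "M", "L")

#: The 27 composite labels in economic-social-environmental order.
ALL_CATEGORIES = tuple(
    "-".join(triple) for triple in itertools.product(LEVELS, repeat=3)
)


def classify_dimension(
    values: np.ndarray,
    lower_q: float = 25.0,
    upper_q: float = 75.0,
) -> np.ndarray:
    """Label each value L / M / H against the pooled quartile thresholds.

    Quantiles use linear interpolation between order statistics.  When the
    two thresholds coincide (constant or near-constant input) every unit is
    Medium and a warning is emitted.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 4:
        raise ValueError("need at least 4 units to form quartile classes")
    if np.any(~np.isfinite(values)):
        raise ValueError("non-finite access values")
    q25, q75 = np.percentile(values, [lower_q, upper_q])
    if q25 == q75:
        warnings.warn(
            "degenerate quantile thresholds (q25 == q75); all units classed M",
            stacklevel=2,
        )
        return np.full(values.shape, "M", dtype="<U1")
    out = np.full(values.shape, "M", dtype="<U1")
    out[values < q25] = "L"
    out[values > q75] = "H"
    return out


def composite_category(levels: tuple[str, str, str]) -> str:
    """Join (economic, social, environmental) levels into the category label."""
    if len(levels) != 3 or any(l not in LEVELS for l in levels):
        raise ValueError(f"invalid level triple: {levels!r}")
    return "-".join(levels)


def assign_class(levels: tuple[str, str, str]) -> str:
    """General class of a level triple.

    I if no dimension is Low; otherwise II if at least one dimension is
    High; otherwise III.  The three predicates partition all 27 triples.
    """
    if len(levels) != 3 or any(l not in LEVELS for l in levels):
        raise ValueError(f"invalid level triple: {levels!r}")
    if "L" not in levels:
        return "I"
    if "H" in levels:
        return "II"
    return "III"


def classify_units(access: pd.DataFrame, level: str = "country") -> pd.DataFrame:
    """Composite classification of every unit at one administrative level.

    ``access`` must be a normalized access table with columns
    ``unit_id, level, category, ie_norm`` covering the three categories.
    Returns one row per unit: per-dimension levels, the composite label and
    the general class.
    """
    sub = access[access["level"] == level]
    wide = sub.pivot(index="unit_id", columns="category", values="ie_norm")
    missing = [c for c in ("economic", "social", "environmental") if c not in wide.columns]
    if missing:
        raise ValueError(f"access table lacks categories: {missing}")
    wide = wide.dropna(subset=["economic", "social", "environmental"])
    levels = {}
    for cat in ("economic", "social", "environmental"):
        levels[cat] = classify_dimension(wide[cat].to_numpy())
    out = pd.DataFrame(
        {
            "unit_id": wide.index.to_numpy(),
            "level": level,
            "econ_level": levels["economic"],
            "soc_level": levels["social"],
            "env_level": levels["environmental"],
        }
    )
    triples = list(zip(out["econ_level"], out["soc_level"], out["env_level"]))
    out["category"] = [composite_category(t) for t in triples]
    out["general_class"] = [assign_class(t) for t in triples]
    return out
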