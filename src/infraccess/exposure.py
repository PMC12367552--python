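"""Population-weighted infrastructure access per administrative unit.

The access statistic for a unit is

    IE = sum_i(P_i * I_i) / sum_i(P_i)

over the unit's grid cells — the infrastructure level experienced by the
average resident, which up-weights infrastructure located where people are.
Per level and category, IE is then normalized by the 95th percentile across
units, with values above the percentile capped at 1.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from infraccess.admin import AdminPartition
from infraccess.grid import GridLayer

__all__ = ["population_weighted_access", "normalize_access", "access_bias"]

log = logging.getLogger(__name__)


def _unit_cell_arrays(
    pop: GridLayer,
    infra: GridLayer,
    partition: AdminPartition,
    level: str,
    treat_missing_as_zero: bool = False,
):
    """Flatten the grids to (unit id, population, infrastructure) cell triples.

    By default a cell enters the sums only where both population and
    infrastructure are valid; with ``treat_missing_as_zero`` a cell with
    valid population but masked infrastructure contributes its population
    weight with infrastructure value 0.
    """
    pop.require_same_grid(infra, "infrastructure")
    if pop.shape != partition.unit_ids.shape:
        raise ValueError(
            f"partition shape {partition.unit_ids.shape} != grid shape {pop.shape}"
        )
    ids = partition.ids_at(level)
    if treat_missing_as_zero:
        keep = pop.mask & (ids > 0)
        ivals = np.where(infra.mask, infra.values, 0.0)
    else:
        keep = pop.mask & infra.mask & (ids > 0)
        ivals = infra.values
    return ids[keep], pop.values[keep], ivals[keep]


def _weighted_means(ids, weights, values) -> pd.DataFrame:
    frame = pd.DataFrame({"unit_id": ids, "w": weights, "wx": weights * values, "x": values})
    grouped = frame.groupby("unit_id").agg(
        total_pop=("w", "sum"),
        wx=("wx", "sum"),
        unweighted=("x", "mean"),
        n_cells=("x", "size"),
    )
    return grouped


def population_weighted_access(
    pop: GridLayer,
    infra: GridLayer,
    partition: AdminPartition,
    level: str = "country",
    treat_missing_as_zero: bool = False,
) -> pd.DataFrame:
    """Raw population-weighted access per unit.

    Returns a frame with columns ``unit_id, ie_raw, total_pop, n_cells``.
    Units with zero total population (or no usable cells) are excluded with
    a logged warning rather than propagating NaNs downstream.
    """
    if np.any(pop.values[pop.mask] < 0):
        raise ValueError("population must be non-negative")
    ids, w, x = _unit_cell_arrays(pop, infra, partition, level, treat_missing_as_zero)
    grouped = _weighted_means(ids, w, x)
    bad = grouped[grouped["total_pop"] <= 0]
    if len(bad):
        log.warning(
            "excluding %d unit(s) with zero total population at level %s: %s",
            len(bad), level, bad.index.tolist()[:10],
        )
        grouped = grouped[grouped["total_pop"] > 0]
    all_units = set(partition.units_at(level)["unit_id"].tolist())
    missing = all_units - set(grouped.index.tolist())
    if missing:
        log.warning(
            "%d unit(s) at level %s have no usable cells: %s",
            len(missing), level, sorted(missing)[:10],
        )
    out = grouped.reset_index()
    out["ie_raw"] = out["wx"] / out["total_pop"]
    return out[["unit_id", "ie_raw", "total_pop", "n_cells"]]


def normalize_access(
    raw: pd.DataFrame,
    level: str,
    category: str,
    percentile: float = 95.0,
) -> pd.DataFrame:
    """95th-percentile normalization with capping at 1.

    The percentile is computed over all units of the same level and category
    (linear interpolation between order statistics) and ``ie_norm`` is
    ``min(ie_raw / q95, 1)``.
    """
    if len(raw) < 2:
        raise ValueError("need at least 2 units to normalize")
    q = float(np.percentile(raw["ie_raw"].to_numpy(), percentile))
    if q <= 0:
        raise ValueError(f"degenerate access distribution: P{percentile:g} = {q}")
    out = raw.copy()
    out["level"] = level
    out["category"] = category
    out["ie_norm"] = np.minimum(out["ie_raw"] / q, 1.0)
    return out[["unit_id", "level", "category", "ie_raw", "ie_norm"]]


def access_bias(
    pop: GridLayer,
    infra: GridLayer,
    partition: AdminPartition,
    level: str = "country",
) -> pd.DataFrame:
    """Population-weighted minus unweighted mean access per unit.

    Positive values flag units where people cluster near infrastructure
    (an unweighted mean would understate what residents experience);
    negative values flag units where population sits far from it.
    """
    ids, w, x = _unit_cell_arrays(pop, infra, partition, level)
    grouped = _weighted_means(ids, w, x)
    grouped = grouped[grouped["total_pop"] > 0]
    out = grouped.reset_index()
    out["delta"] = out["wx"] / out["total_pop"] - out["unweighted"]
    return out[["unit_id", "delta"]]
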