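"""Within-unit inequality of infrastructure access.

The primary measure is a population-weighted Gini coefficient: cells are
sorted by access, the Lorenz curve plots cumulative population share against
cumulative share of population-weighted access (sum of pop * access), and
the Gini is one minus twice the trapezoid-rule area under the curve.  Zero
means every population-bearing cell sees the same access; values approach 1
as access concentrates on a vanishing share of the population.

An auxiliary index — half the population-weighted relative mean absolute
deviation, clipped to [0, 1] — is provided as a pluggable second measure of
spatial inequality with the same 0 (equality) to 1 (concentration)
orientation.
"""

from __future__ import annotations

import logging
from typing import Callable

import numpy as np
import pandas as pd

from infraccess.admin import AdminPartition
from infraccess.grid import GridLayer

__all__ = ["weighted_gini", "inequality_index", "unit_inequality"]

log = logging.getLogger(__name__)


def _check_inputs(pop: np.ndarray, access: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    pop = np.asarray(pop, dtype=float).ravel()
    access = np.asarray(access, dtype=float).ravel()
    if pop.shape != access.shape:
        raise ValueError("pop and access must have identical length")
    if np.any(pop < 0) or np.any(access < 0):
        raise ValueError("pop and access must be non-negative")
    if pop.sum() <= 0:
        raise ValueError("total population must be positive")
    return pop, access


def weighted_gini(pop: np.ndarray, access: np.ndarray) -> float:
    """Population-weighted Gini coefficient of per-cell access values.

    Lorenz construction with trapezoid integration; cells tied on access are
    grouped first, so input order never affects the result.  All-zero access
    is treated as perfect equality (0) with a logged note.
    """
    pop, access = _check_inputs(pop, access)
    keep = pop > 0
    pop, access = pop[keep], access[keep]
    total_access = float((pop * access).sum())
    if total_access == 0:
        log.info("all-zero access: Gini defined as 0")
        return 0.0
    order = np.argsort(access, kind="stable")
    a, p = access[order], pop[order]
    # group ties so the Lorenz polyline has one vertex per distinct value
    uniq, inverse = np.unique(a, return_inverse=True)
    pw = np.bincount(inverse, weights=p)
    yw = np.bincount(inverse, weights=p * a)
    x = np.concatenate(([0.0], np.cumsum(pw) / pw.sum()))
    y = np.concatenate(([0.0], np.cumsum(yw) / yw.sum()))
    area = float(np.trapezoid(y, x))
    return 1.0 - 2.0 * area


def inequality_index(pop: np.ndarray, access: np.ndarray) -> float:
    """Auxiliary spatial-inequality index in [0, 1].

    Half the population-weighted relative mean absolute deviation,

        0.5 * sum_i p_i |a_i - a_bar| / (sum_i p_i * a_bar),

    with ``a_bar`` the population-weighted mean access; clipped to [0, 1].
    0 is absolute equality; the index approaches 1 as all access mass lands
    on a vanishing population share.
    """
    pop, access = _check_inputs(pop, access)
    keep = pop > 0
    pop, access = pop[keep], access[keep]
    mean = float((pop * access).sum() / pop.sum())
    if mean == 0:
        log.info("all-zero access: inequality index defined as 0")
        return 0.0
    rmad = float((pop * np.abs(access - mean)).sum() / (pop.sum() * mean))
    return float(np.clip(0.5 * rmad, 0.0, 1.0))


def unit_inequality(
    pop: GridLayer,
    infra: GridLayer,
    partition: AdminPartition,
    level: str = "country",
    category: str = "economic",
    include_inq: bool = True,
    inq_fn: Callable[[np.ndarray, np.ndarray], float] | None = None,
) -> pd.DataFrame:
    """Per-unit Gini (and optional auxiliary index) of access to one layer.

    ``inq_fn`` substitutes the auxiliary measure; the default is
    :func:`inequality_index`.  Single-cell units get Gini 0 and are flagged
    in the ``degenerate`` column.
    """
    pop.require_same_grid(infra, "infrastructure")
    if pop.shape != partition.unit_ids.shape:
        raise ValueError("partition not aligned to grids")
    ids = partition.ids_at(level)
    keep = pop.mask & infra.mask & (ids > 0) & (pop.values > 0)
    frame = pd.DataFrame(
        {"unit_id": ids[keep], "pop": pop.values[keep], "access": infra.values[keep]}
    )
    fn = inq_fn if inq_fn is not None else inequality_index
    rows = []
    for unit_id, grp in frame.groupby("unit_id"):
        degenerate = len(grp) < 2
        if degenerate:
            gini, inq = 0.0, 0.0
        else:
            gini = weighted_gini(grp["pop"].to_numpy(), grp["access"].to_numpy())
            inq = fn(grp["pop"].to_numpy(), grp["access"].to_numpy()) if include_inq else np.nan
        rows.append(
            {
                "unit_id": int(unit_id),
                "level": level,
                "category": category,
                "gini": gini,
                "inq": inq if include_inq else np.nan,
                "degenerate": degenerate,
            }
        )
    return pd.DataFrame(rows)
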