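"""Administrative partitions: a unit-ID raster plus a unit metadata table.

The ID field stores the finest administrative level (counties); country
membership is recovered through each county's ``parent_unit_id``.  Countries
carry a region and a North/South group used for the cross-country
comparisons and the mixed-model random intercepts.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from infraccess.grid import GridLayer, read_layer, write_layer

__all__ = ["AdminPartition", "UNIT_COLUMNS"]

UNIT_COLUMNS = ["unit_id", "name", "level", "region", "group", "parent_unit_id"]


@dataclass
class AdminPartition:
    """Integer unit-ID field aligned to the analysis grid plus metadata.

    ``unit_ids`` holds county-level IDs (0 = outside any unit).  ``units``
    has one row per unit at every level with columns
    ``unit_id, name, level, region, group, parent_unit_id``.
    """

    unit_ids: np.ndarray
    units: pd.DataFrame
    cell_size_deg: float = 0.1
    origin: tuple[float, float] = (90.0, -180.0)

    def __post_init__(self) -> None:
        self.unit_ids = np.asarray(self.unit_ids, dtype=np.int64)
        if self.unit_ids.ndim != 2:
            raise ValueError("unit_ids must be 2-D")
        self.units = self.units.reset_index(drop=True)
        self.validate()

    def validate(self) -> None:
        missing = set(UNIT_COLUMNS) - set(self.units.columns)
        if missing:
            raise ValueError(f"units table missing columns: {sorted(missing)}")
        ids = self.units["unit_id"].to_numpy()
        if len(np.unique(ids)) != len(ids):
            raise ValueError("duplicate unit_id in units table")
        field_ids = np.unique(self.unit_ids)
        field_ids = field_ids[field_ids > 0]
        unknown = set(field_ids.tolist()) - set(ids.tolist())
        if unknown:
            raise ValueError(f"unit ids present in field but not in table: {sorted(unknown)[:5]}")
        counties = self.units[self.units["level"] == "county"]
        countries = set(
            self.units.loc[self.units["level"] == "country", "unit_id"].tolist()
        )
        bad = counties[~counties["parent_unit_id"].isin(countries)]
        if len(bad):
            raise ValueError(
                f"counties with invalid parent country: {bad['unit_id'].tolist()[:5]}"
            )

    @property
    def levels(self) -> list[str]:
        return sorted(self.units["level"].unique().tolist())

    def units_at(self, level: str) -> pd.DataFrame:
        """Metadata rows for one administrative level."""
        if level not in ("country", "county"):
            raise ValueError(f"unknown level {level!r}")
        return self.units[self.units["level"] == level].reset_index(drop=True)

    def ids_at(self, level: str) -> np.ndarray:
        """Unit-ID field at the requested level.

        County cells are re-labelled with their parent country when
        ``level == 'country'``.
        """
        if level == "county":
            return self.unit_ids
        if level != "country":
            raise ValueError(f"unknown level {level!r}")
        mapping = self._to_country_map()
        out = mapping[self.unit_ids]
        return out

    def _to_country_map(self) -> np.ndarray:
        max_id = int(self.units["unit_id"].max())
        mapping = np.zeros(max_id + 1, dtype=np.int64)
        for _, row in self.units.iterrows():
            uid = int(row["unit_id"])
            if row["level"] == "country":
                mapping[uid] = uid
            else:
                mapping[uid] = int(row["parent_unit_id"])
        return mapping

    def country_of(self) -> dict[int, int]:
        """Mapping county unit_id -> parent country unit_id (countries map to self)."""
        out: dict[int, int] = {}
        for _, row in self.units.iterrows():
            uid = int(row["unit_id"])
            out[uid] = uid if row["level"] == "country" else int(row["parent_unit_id"])
        return out

    # ------------------------------------------------------------------ I/O

    def write(self, raster_path: str | Path, table_path: str | Path) -> None:
        layer = GridLayer(
            values=self.unit_ids.astype(float),
            mask=np.ones_like(self.unit_ids, dtype=bool),
            cell_size_deg=self.cell_size_deg,
            origin=self.origin,
        )
        write_layer(layer, raster_path)
        self.units[UNIT_COLUMNS].to_csv(table_path, index=False)

    @classmethod
    def read(cls, raster_path: str | Path, table_path: str | Path) -> "AdminPartition":
        layer = read_layer(raster_path)
        units = pd.read_csv(table_path)
        # parent_unit_id is NaN for countries in CSV round trips
        units["parent_unit_id"] = units["parent_unit_id"].fillna(0).astype(int)
        return cls(
            unit_ids=np.rint(layer.values).astype(np.int64),
            units=units,
            cell_size_deg=layer.cell_size_deg,
            origin=layer.origin,
        )
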