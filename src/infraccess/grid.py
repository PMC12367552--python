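"""Regular lat/lon grid layers with explicit missing-data masks.

A :class:`GridLayer` is the unit of all mapping computation: a 2-D value
field on a regular geographic grid, oriented so latitude decreases with the
row index (row 0 is the northern edge).  Cell identity is (row, col) from
the upper-left origin, and masked-out cells are excluded from every
reduction.

Two on-disk formats are supported:

* ESRI ASCII grid (``.asc``/``.txt``) — plain text, self-describing,
  round-trips values bit-exactly (floats are written with 17 significant
  digits).
* TIFF (``.tif``/``.tiff``) via :mod:`tifffile` — georeferencing (cell size,
  origin, nodata) is carried in a JSON ``ImageDescription`` tag.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["GridLayer", "read_layer", "write_layer", "align_stack"]

_DEFAULT_NODATA = -9999.0


@dataclass
class GridLayer:
    """A real-valued field on a regular lat/lon grid with a validity mask.

    Parameters
    ----------
    values
        2-D float array of cell values.  Content of masked cells is
        unspecified.
    mask
        2-D boolean array, ``True`` where the cell holds valid data.
    cell_size_deg
        Cell edge length in degrees (square cells).
    origin
        ``(lat, lon)`` of the grid's upper-left corner.
    """

    values: np.ndarray
    mask: np.ndarray = None  # type: ignore[assignment]
    cell_size_deg: float = 0.1
    origin: tuple[float, float] = (90.0, -180.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D")
        if self.mask is None:
            self.mask = np.isfinite(self.values)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.values.shape:
            raise ValueError(
                f"mask shape {self.mask.shape} != values shape {self.values.shape}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def n_valid(self) -> int:
        return int(self.mask.sum())

    def valid_values(self) -> np.ndarray:
        """Return the 1-D array of values at valid cells."""
        return self.values[self.mask]

    def copy_with(self, values: np.ndarray, mask: np.ndarray | None = None) -> "GridLayer":
        """New layer on the same grid with replaced values (and optionally mask)."""
        return GridLayer(
            values=np.array(values, dtype=float),
            mask=self.mask.copy() if mask is None else np.asarray(mask, dtype=bool),
            cell_size_deg=self.cell_size_deg,
            origin=self.origin,
        )

    def same_grid(self, other: "GridLayer") -> bool:
        return (
            self.shape == other.shape
            and math.isclose(self.cell_size_deg, other.cell_size_deg, rel_tol=1e-9)
            and math.isclose(self.origin[0], other.origin[0], abs_tol=1e-9)
            and math.isclose(self.origin[1], other.origin[1], abs_tol=1e-9)
        )

    def require_same_grid(self, other: "GridLayer", what: str = "layer") -> None:
        if not self.same_grid(other):
            raise ValueError(
                f"{what} is not aligned: shape {other.shape} vs {self.shape}, "
                f"cell {other.cell_size_deg} vs {self.cell_size_deg}, "
                f"origin {other.origin} vs {self.origin}"
            )


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix in (".asc", ".txt"):
        return "asc"
    if suffix in (".tif", ".tiff"):
        return "tif"
    raise ValueError(f"unsupported raster format: {path}")


def read_layer(path: str | Path, band: int = 0) -> GridLayer:
    """Read a gridded layer from disk, masking nodata cells.

    Parameters
    ----------
    path
        ESRI ASCII grid or TIFF file.
    band
        Band index for multi-band TIFFs (ignored for ASCII grids, which are
        single-band by construction).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if _infer_format(path) == "asc":
        return _read_asc(path)
    return _read_tif(path, band)


def write_layer(layer: GridLayer, path: str | Path, nodata: float = _DEFAULT_NODATA) -> Path:
    """Write a layer to disk, encoding masked cells as ``nodata``."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if np.any(layer.values[layer.mask] == nodata):
        raise ValueError(f"valid cell collides with nodata value {nodata}")
    if _infer_format(path) == "asc":
        _write_asc(layer, path, nodata)
    else:
        _write_tif(layer, path, nodata)
    return path


def _read_asc(path: Path) -> GridLayer:
    header: dict[str, float] = {}
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            key = parts[0].lower()
            if key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"):
                header[key] = float(parts[1])
            else:
                rows.append([float(tok) for tok in parts])
    for req in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if req not in header:
            raise ValueError(f"{path}: missing ASCII-grid header field {req}")
    values = np.array(rows, dtype=float)
    nrows, ncols = int(header["nrows"]), int(header["ncols"])
    if values.shape != (nrows, ncols):
        raise ValueError(f"{path}: data block {values.shape} != header ({nrows}, {ncols})")
    nodata = header.get("nodata_value", _DEFAULT_NODATA)
    mask = values != nodata
    top_lat = header["yllcorner"] + nrows * header["cellsize"]
    return GridLayer(
        values=values,
        mask=mask,
        cell_size_deg=header["cellsize"],
        origin=(top_lat, header["xllcorner"]),
    )


def _write_asc(layer: GridLayer, path: Path, nodata: float) -> None:
    nrows, ncols = layer.shape
    out = np.where(layer.mask, layer.values, nodata)
    with open(path, "w") as fh:
        fh.write(f"ncols {ncols}\n")
        fh.write(f"nrows {nrows}\n")
        fh.write(f"xllcorner {float(layer.origin[1])!r}\n")
        fh.write(f"yllcorner {float(layer.origin[0]) - nrows * float(layer.cell_size_deg)!r}\n")
        fh.write(f"cellsize {float(layer.cell_size_deg)!r}\n")
        fh.write(f"NODATA_value {float(nodata)!r}\n")
        for row in out:
            # repr of a Python float is its shortest exact round-trip form
            fh.write(" ".join(repr(float(v)) for v in row))
            fh.write("\n")


def _read_tif(path: Path, band: int) -> GridLayer:
    import tifffile

    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        desc = tif.pages[0].description or "{}"
    try:
        meta = json.loads(desc)
    except json.JSONDecodeError:
        meta = {}
    if data.ndim == 3:
        if not 0 <= band < data.shape[0]:
            raise IndexError(f"band {band} out of range for {data.shape[0]}-band raster")
        data = data[band]
    elif band not in (0, None):
        raise IndexError(f"band {band} requested from single-band raster")
    values = np.asarray(data, dtype=float)
    nodata = meta.get("nodata", _DEFAULT_NODATA)
    mask = values != nodata
    return GridLayer(
        values=values,
        mask=mask,
        cell_size_deg=float(meta.get("cell_size_deg", 0.1)),
        origin=tuple(meta.get("origin", (90.0, -180.0))),
    )


def _write_tif(layer: GridLayer, path: Path, nodata: float) -> None:
    import tifffile

    out = np.where(layer.mask, layer.values, nodata)
    meta = {
        "cell_size_deg": layer.cell_size_deg,
        "origin": list(layer.origin),
        "nodata": nodata,
    }
    tifffile.imwrite(path, out, description=json.dumps(meta))


def align_stack(layers: list[GridLayer]) -> list[GridLayer]:
    """Bring layers onto the coarsest common grid by block-mean downsampling.

    All layers must share the upper-left origin, and every cell size must be
    an integer multiple of the finest — equivalently, the coarsest cell size
    must be an integer multiple of each layer's.  Finer layers are
    block-averaged over their valid child cells; a coarse cell is masked only
    when every child is masked.
    """
    if not layers:
        raise ValueError("empty layer list")
    origin = layers[0].origin
    for layer in layers[1:]:
        if not (
            math.isclose(layer.origin[0], origin[0], abs_tol=1e-9)
            and math.isclose(layer.origin[1], origin[1], abs_tol=1e-9)
        ):
            raise ValueError("layers do not share an origin")
    coarsest = max(layer.cell_size_deg for layer in layers)
    out = []
    for layer in layers:
        ratio = coarsest / layer.cell_size_deg
        k = round(ratio)
        if not math.isclose(ratio, k, rel_tol=1e-9) or k < 1:
            raise ValueError(
                f"cell size {layer.cell_size_deg} is not an integer divisor of {coarsest}"
            )
        if k == 1:
            out.append(layer)
            continue
        out.append(_block_mean(layer, k, coarsest))
    shapes = {layer.shape for layer in out}
    if len(shapes) != 1:
        raise ValueError(f"aligned layers disagree on extent: {sorted(shapes)}")
    return out


def _block_mean(layer: GridLayer, k: int, coarse_cell: float) -> GridLayer:
    nrows, ncols = layer.shape
    if nrows % k or ncols % k:
        raise ValueError(f"grid shape {layer.shape} not divisible by block size {k}")
    vals = np.where(layer.mask, layer.values, 0.0)
    vals4 = vals.reshape(nrows // k, k, ncols // k, k)
    mask4 = layer.mask.reshape(nrows // k, k, ncols // k, k)
    counts = mask4.sum(axis=(1, 3))
    sums = vals4.sum(axis=(1, 3))
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return GridLayer(
        values=means,
        mask=counts > 0,
        cell_size_deg=coarse_cell,
        origin=layer.origin,
    )
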