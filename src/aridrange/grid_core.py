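"""Raster data model, I/O, grid alignment and point extraction.

All stages of the pipeline share one gridded data model: a :class:`GridSpec`
describing a regular, axis-aligned, cell-centre-registered grid in projected
map coordinates (x grows east, y grows north, row 0 is the northernmost row),
:class:`RasterLayer` holding one named variable on such a grid, and
:class:`RasterStack` bundling aligned layers.

Cells are half-open: cell (i, j) covers
``[x0 + j*dx, x0 + (j+1)*dx) x (y0 - (i+1)*dy, y0 - i*dy]``
so every point maps to exactly one cell; points on the outer max-x/min-y
boundary of the full grid are assigned to the last cell.

Supported file formats are ESRI ASCII grids (plain text, square cells) and
single-band GeoTIFF (via tifffile, using the ModelPixelScale/ModelTiepoint
GeoTIFF tags and NaN-coded nodata with a GDAL_NODATA tag).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GridSpec",
    "RasterLayer",
    "RasterStack",
    "RasterFormatError",
    "CoverageError",
    "AlignmentError",
    "read_raster",
    "write_raster",
    "align_to_grid",
    "extract_at_points",
    "load_occurrences",
    "validate_occurrences",
]

logger = logging.getLogger(__name__)


class RasterFormatError(ValueError):
    """A raster file does not parse under the named standard."""


class CoverageError(ValueError):
    """Source and target grids do not overlap spatially."""


class AlignmentError(ValueError):
    """Layers expected to share one GridSpec do not."""


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a regular raster grid.

    ``x_origin``/``y_origin`` are the map coordinates of the *outer* corner of
    cell (0, 0), i.e. the west edge of column 0 and the north edge of row 0.
    Values are registered to cell centres.
    """

    n_rows: int
    n_cols: int
    x_origin: float
    y_origin: float
    cell_size_x: float
    cell_size_y: float

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and one column")
        if self.cell_size_x <= 0 or self.cell_size_y <= 0:
            raise ValueError("cell sizes must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    def x_centers(self) -> np.ndarray:
        return self.x_origin + (np.arange(self.n_cols) + 0.5) * self.cell_size_x

    def y_centers(self) -> np.ndarray:
        return self.y_origin - (np.arange(self.n_rows) + 0.5) * self.cell_size_y

    @property
    def x_max(self) -> float:
        return self.x_origin + self.n_cols * self.cell_size_x

    @property
    def y_min(self) -> float:
        return self.y_origin - self.n_rows * self.cell_size_y

    def point_to_cell(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Map point coordinates to (row, col) indices.

        Returns ``(row, col, inside)``; ``row``/``col`` are only meaningful
        where ``inside`` is True.  Half-open cell semantics; points exactly on
        the grid's max-x or min-y outer boundary belong to the last cell.
        """
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        tx = (x - self.x_origin) / self.cell_size_x
        ty = (self.y_origin - y) / self.cell_size_y
        col = np.floor(tx).astype(np.int64)
        row = np.floor(ty).astype(np.int64)
        # outer boundary: x == x_max or y == y_min snap into the last cell
        col = np.where((x == self.x_max), self.n_cols - 1, col)
        row = np.where((y == self.y_min), self.n_rows - 1, row)
        inside = (col >= 0) & (col < self.n_cols) & (row >= 0) & (row < self.n_rows)
        return row, col, inside

    def is_aligned(self, other: "GridSpec") -> bool:
        """Two grids are aligned iff all six fields match exactly."""
        return self == other

    def looks_geographic(self) -> bool:
        """Heuristic: does this grid look like an unprojected lon/lat grid?

        A grid whose origin sits inside the lon/lat bounding box and whose
        cells are smaller than half a degree is almost certainly in degrees.
        """
        return (
            abs(self.x_origin) <= 360.0
            and abs(self.y_origin) <= 90.0
            and self.cell_size_x < 0.5
            and self.cell_size_y < 0.5
        )


@dataclass
class RasterLayer:
    """One named variable on a grid; ``mask`` is True on nodata cells."""

    name: str
    grid: GridSpec
    values: np.ndarray
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.mask is None:
            self.mask = np.zeros(self.grid.shape, dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"layer {self.name!r}: values shape {self.values.shape} "
                f"!= grid shape {self.grid.shape}"
            )
        if self.mask.shape != self.grid.shape:
            raise ValueError(f"layer {self.name!r}: mask shape mismatch")
        if not np.all(np.isfinite(self.values[~self.mask])):
            raise ValueError(
                f"layer {self.name!r}: non-finite values outside the nodata mask"
            )

    def copy(self, name: str | None = None) -> "RasterLayer":
        return RasterLayer(
            name if name is not None else self.name,
            self.grid,
            self.values.copy(),
            self.mask.copy(),
        )

    def equals(self, other: "RasterLayer", rtol: float = 0.0, atol: float = 0.0) -> bool:
        return (
            self.grid == other.grid
            and np.array_equal(self.mask, other.mask)
            and np.allclose(
                self.values[~self.mask], other.values[~other.mask], rtol=rtol, atol=atol
            )
        )


class RasterStack:
    """Ordered collection of aligned, uniquely named layers."""

    def __init__(self, layers: Sequence[RasterLayer]):
        layers = list(layers)
        if not layers:
            raise ValueError("a stack needs at least one layer")
        grid = layers[0].grid
        names = [lyr.name for lyr in layers]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate layer names: {names}")
        for lyr in layers:
            if lyr.grid != grid:
                raise AlignmentError(
                    f"layer {lyr.name!r} is not on the shared grid"
                )
        self._layers = layers
        self._index = {name: i for i, name in enumerate(names)}

    @property
    def grid(self) -> GridSpec:
        return self._layers[0].grid

    @property
    def names(self) -> list[str]:
        return [lyr.name for lyr in self._layers]

    def __len__(self) -> int:
        return len(self._layers)

    def __iter__(self) -> Iterator[RasterLayer]:
        return iter(self._layers)

    def __contains__(self, name: str) -> bool:
        return name in self._index

    def __getitem__(self, name: str) -> RasterLayer:
        return self._layers[self._index[name]]

    def combined_mask(self) -> np.ndarray:
        """True where *any* layer is nodata."""
        mask = np.zeros(self.grid.shape, dtype=bool)
        for lyr in self._layers:
            mask |= lyr.mask
        return mask

    def subset(self, names: Sequence[str]) -> "RasterStack":
        return RasterStack([self[n] for n in names])

    def replace(self, layers: Sequence[RasterLayer]) -> "RasterStack":
        """New stack where layers with matching names are replaced."""
        new = {lyr.name: lyr for lyr in layers}
        return RasterStack([new.get(lyr.name, lyr) for lyr in self._layers])

    def to_table(self) -> pd.DataFrame:
        """Off-mask cells as rows, one column per variable plus row/col."""
        mask = self.combined_mask()
        rows, cols = np.nonzero(~mask)
        data = {"row": rows, "col": cols}
        for lyr in self._layers:
            data[lyr.name] = lyr.values[rows, cols]
        return pd.DataFrame(data)


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

_ASCII_NODATA = -9999.0
_ASCII_DECIMALS = 6

# GeoTIFF tag codes
_TAG_MODEL_PIXEL_SCALE = 33550
_TAG_MODEL_TIEPOINT = 33922
_TAG_GDAL_NODATA = 42113


def _infer_format(path: str | Path, fmt: str | None) -> str:
    if fmt is not None:
        if fmt not in ("geotiff", "esri_ascii"):
            raise ValueError(f"unknown raster format {fmt!r}")
        return fmt
    suffix = Path(path).suffix.lower()
    if suffix in (".tif", ".tiff"):
        return "geotiff"
    if suffix in (".asc", ".txt"):
        return "esri_ascii"
    raise ValueError(f"cannot infer raster format from {path!r}; pass format=")


def read_raster(path: str | Path, format: str | None = None, name: str | None = None) -> RasterLayer:
    """Read a single-band raster (ESRI ASCII grid or GeoTIFF).

    The returned layer's name defaults to the file stem.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    if name is None:
        name = path.stem
    if fmt == "esri_ascii":
        return _read_esri_ascii(path, name)
    return _read_geotiff(path, name)


def write_raster(layer: RasterLayer, path: str | Path, format: str | None = None) -> Path:
    """Write a layer; ESRI ASCII at 6 decimals, GeoTIFF as float32."""
    path = Path(path)
    fmt = _infer_format(path, format)
    path.parent.mkdir(parents=True, exist_ok=True)
    if fmt == "esri_ascii":
        _write_esri_ascii(layer, path)
    else:
        _write_geotiff(layer, path)
    logger.info(
        "wrote %s (%s, %dx%d cells, origin %.6g/%.6g, cell %.6g/%.6g)",
        path, fmt, layer.grid.n_rows, layer.grid.n_cols,
        layer.grid.x_origin, layer.grid.y_origin,
        layer.grid.cell_size_x, layer.grid.cell_size_y,
    )
    return path


def _read_esri_ascii(path: Path, name: str) -> RasterLayer:
    header: dict[str, float] = {}
    header_keys = {"ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"}
    with open(path) as fh:
        lines = fh.read().split("\n")
    i = 0
    while i < len(lines):
        parts = lines[i].split()
        if len(parts) == 2 and parts[0].lower() in header_keys:
            try:
                header[parts[0].lower()] = float(parts[1])
            except ValueError as exc:
                raise RasterFormatError(
                    f"{path}: header field {parts[0]!r} has non-numeric value {parts[1]!r}"
                ) from exc
            i += 1
        else:
            break
    for req in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if req not in header:
            raise RasterFormatError(f"{path}: missing required header field {req!r}")
    n_cols = int(header["ncols"])
    n_rows = int(header["nrows"])
    if n_cols != header["ncols"] or n_rows != header["nrows"] or n_cols < 1 or n_rows < 1:
        raise RasterFormatError(f"{path}: ncols/nrows must be positive integers")
    cell = header["cellsize"]
    if cell <= 0:
        raise RasterFormatError(f"{path}: cellsize must be positive")
    nodata = header.get("nodata_value", _ASCII_NODATA)

    body = "\n".join(lines[i:])
    try:
        flat = np.array(body.split(), dtype=float)
    except ValueError as exc:
        raise RasterFormatError(f"{path}: non-numeric cell value in body") from exc
    if flat.size != n_rows * n_cols:
        raise RasterFormatError(
            f"{path}: body has {flat.size} values but header ncols*nrows "
            f"promises {n_rows * n_cols}"
        )
    values = flat.reshape(n_rows, n_cols)
    mask = values == nodata
    values = np.where(mask, np.nan, values)
    grid = GridSpec(
        n_rows=n_rows,
        n_cols=n_cols,
        x_origin=header["xllcorner"],
        y_origin=header["yllcorner"] + n_rows * cell,
        cell_size_x=cell,
        cell_size_y=cell,
    )
    values = np.where(mask, 0.0, values)
    return RasterLayer(name, grid, values, mask)


def _write_esri_ascii(layer: RasterLayer, path: Path) -> None:
    grid = layer.grid
    if not math.isclose(grid.cell_size_x, grid.cell_size_y, rel_tol=1e-12):
        raise ValueError("ESRI ASCII requires square cells; use GeoTIFF instead")
    vals = np.where(layer.mask, _ASCII_NODATA, layer.values)
    with open(path, "w") as fh:
        fh.write(f"ncols {grid.n_cols}\n")
        fh.write(f"nrows {grid.n_rows}\n")
        fh.write(f"xllcorner {grid.x_origin!r}\n")
        fh.write(f"yllcorner {grid.y_min!r}\n")
        fh.write(f"cellsize {grid.cell_size_x!r}\n")
        fh.write(f"NODATA_value {_ASCII_NODATA:g}\n")
        for row in vals:
            fh.write(" ".join(f"{v:.{_ASCII_DECIMALS}f}" for v in row))
            fh.write("\n")


def _read_geotiff(path: Path, name: str) -> RasterLayer:
    import tifffile

    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        values = page.asarray().astype(np.float64)
        tags = page.tags
        if _TAG_MODEL_PIXEL_SCALE not in tags or _TAG_MODEL_TIEPOINT not in tags:
            raise RasterFormatError(
                f"{path}: missing GeoTIFF ModelPixelScale/ModelTiepoint tags"
            )
        scale = tags[_TAG_MODEL_PIXEL_SCALE].value
        tie = tags[_TAG_MODEL_TIEPOINT].value
    if values.ndim != 2:
        raise RasterFormatError(f"{path}: expected a single-band 2-D raster")
    dx, dy = float(scale[0]), float(scale[1])
    # tiepoint maps raster (I, J, K) -> model (X, Y, Z); we write I=J=0
    x_origin = float(tie[3]) - float(tie[0]) * dx
    y_origin = float(tie[4]) + float(tie[1]) * dy
    mask = ~np.isfinite(values)
    grid = GridSpec(
        n_rows=values.shape[0],
        n_cols=values.shape[1],
        x_origin=x_origin,
        y_origin=y_origin,
        cell_size_x=dx,
        cell_size_y=dy,
    )
    return RasterLayer(name, grid, np.where(mask, 0.0, values), mask)


def _write_geotiff(layer: RasterLayer, path: Path) -> None:
    import tifffile

    grid = layer.grid
    data = np.where(layer.mask, np.nan, layer.values).astype(np.float32)
    extratags = [
        (_TAG_MODEL_PIXEL_SCALE, "d", 3, (grid.cell_size_x, grid.cell_size_y, 0.0)),
        (_TAG_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, grid.x_origin, grid.y_origin, 0.0)),
        (_TAG_GDAL_NODATA, "s", 0, "nan"),
    ]
    tifffile.imwrite(path, data, extratags=extratags)


# ---------------------------------------------------------------------------
# Alignment / resampling
# ---------------------------------------------------------------------------

def _nearest_index(centers_frac: np.ndarray, n: int) -> np.ndarray:
    """Round fractional source indices to nearest, ties toward the smaller index."""
    idx = np.ceil(centers_frac - 0.5).astype(np.int64)
    return np.clip(idx, 0, n - 1)


def align_to_grid(layer: RasterLayer, target: GridSpec, method: str = "nearest") -> RasterLayer:
    """Resample ``layer`` onto ``target`` by nearest-cell-centre lookup.

    Each target cell takes the value of the source cell whose centre is
    nearest the target cell centre (ties toward smaller row, then smaller
    column); nodata propagates.  Target cells whose centres fall outside the
    source extent become nodata.
    """
    if method != "nearest":
        raise ValueError(f"unsupported resampling method {method!r}")
    src = layer.grid
    if src == target:
        return layer.copy()
    # spatial overlap check on outer extents
    if (
        target.x_origin >= src.x_max
        or target.x_max <= src.x_origin
        or target.y_origin <= src.y_min
        or target.y_min >= src.y_origin
    ):
        raise CoverageError("source and target grids do not overlap")

    tx = target.x_centers()
    ty = target.y_centers()
    # fractional position of target centres in source index space
    fx = (tx - src.x_origin) / src.cell_size_x - 0.5
    fy = (src.y_origin - ty) / src.cell_size_y - 0.5
    col = _nearest_index(fx, src.n_cols)
    row = _nearest_index(fy, src.n_rows)
    outside_x = (tx < src.x_origin) | (tx > src.x_max)
    outside_y = (ty > src.y_origin) | (ty < src.y_min)

    values = layer.values[np.ix_(row, col)]
    mask = layer.mask[np.ix_(row, col)]
    mask = mask | outside_y[:, None] | outside_x[None, :]
    values = np.where(mask, 0.0, values)
    return RasterLayer(layer.name, target, values, mask)


# ---------------------------------------------------------------------------
# Occurrence tables and point extraction
# ---------------------------------------------------------------------------

OCCURRENCE_COLUMNS = ["site_id", "x", "y", "species", "presence"]


def validate_occurrences(table: pd.DataFrame) -> pd.DataFrame:
    """Validate an occurrence table (site_id, x, y, species, presence)."""
    missing = [c for c in OCCURRENCE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"occurrence table is missing columns {missing}")
    presence = table["presence"]
    if not np.isin(presence.to_numpy(), (0, 1)).all():
        raise ValueError("presence must be strictly binary (0/1)")
    dup = table.duplicated(subset=["species", "site_id"])
    if dup.any():
        raise ValueError(
            f"site_id must be unique per species; {int(dup.sum())} duplicates"
        )
    return table


def load_occurrences(path: str | Path) -> pd.DataFrame:
    """Read an occurrence CSV with header ``site_id,x,y,species,presence``."""
    return validate_occurrences(pd.read_csv(path))


def extract_at_points(
    stack: RasterStack, table: pd.DataFrame
) -> tuple[pd.DataFrame, int]:
    """Attach predictor values at each survey site.

    Returns ``(design, n_excluded)`` where ``design`` keeps the occurrence
    columns plus one column per stack variable, in the input row order.
    Sites outside the grid extent or on nodata cells are excluded (with a
    logged count); included rows + excluded = input rows.
    """
    validate_occurrences(table)
    grid = stack.grid
    row, col, inside = grid.point_to_cell(
        table["x"].to_numpy(float), table["y"].to_numpy(float)
    )
    mask = stack.combined_mask()
    on_nodata = np.zeros(len(table), dtype=bool)
    on_nodata[inside] = mask[row[inside], col[inside]]
    keep = inside & ~on_nodata

    n_outside = int((~inside).sum())
    n_nodata = int(on_nodata.sum())
    if n_outside:
        logger.warning("%d site(s) outside the grid extent were excluded", n_outside)
    if n_nodata:
        logger.info("%d site(s) on nodata cells were excluded", n_nodata)

    design = table.loc[keep].reset_index(drop=True).copy()
    r, c = row[keep], col[keep]
    for lyr in stack:
        design[lyr.name] = lyr.values[r, c]
    return design, n_outside + n_nodata
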