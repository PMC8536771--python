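"""Raster data model, I/O and grid preprocessing.

Grids are stored row-major with cell ``(0, 0)`` at the **top-left** corner of
the array, while :attr:`RasterGrid.origin` is the world coordinate of the
grid's **lower-left** corner — the usual GIS raster convention. Every module
of the pipeline shares this convention.

Supported on-disk formats are single-band GeoTIFF (via :mod:`tifffile`, with
``ModelPixelScale``/``ModelTiepoint`` georeferencing tags and the GDAL nodata
tag) and the ESRI ASCII grid (``NCOLS``/``NROWS``/``XLLCORNER``/``YLLCORNER``/
``CELLSIZE``/``NODATA_VALUE`` header followed by rows top to bottom).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import shapely
import tifffile

__all__ = [
    "RasterGrid",
    "ReclassTable",
    "reclassify",
    "resample",
    "mosaic_and_mask",
    "read_raster",
    "write_raster",
]

# GeoTIFF tag codes used for minimal georeferencing.
_TAG_MODEL_PIXEL_SCALE = 33550
_TAG_MODEL_TIEPOINT = 33922
_TAG_GDAL_NODATA = 42113

DEFAULT_NODATA = -9999.0


@dataclass
class RasterGrid:
    """A georeferenced single-band grid of values.

    Parameters
    ----------
    values
        2-D array; integer dtype for categorical grids, float for continuous.
    cell_size
        Edge length of a (square) cell in metres; strictly positive.
    origin
        ``(x, y)`` world coordinate of the lower-left corner of the grid.
    nodata
        Sentinel marking missing cells; propagated, never interpolated.
    """

    values: np.ndarray
    cell_size: float
    origin: tuple[float, float] = (0.0, 0.0)
    nodata: float = DEFAULT_NODATA

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2 or self.values.size == 0:
            raise ValueError("raster values must be a non-empty 2-D array")
        if not self.cell_size > 0:
            raise ValueError(f"cell_size must be > 0, got {self.cell_size}")
        data = self.values[~self.nodata_mask()]
        if data.size and not np.all(np.isfinite(data.astype(float))):
            raise ValueError("non-nodata raster values must be finite")

    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def nodata_mask(self) -> np.ndarray:
        """Boolean mask of nodata cells (NaN cells always count as nodata)."""
        mask = self.values == self.nodata
        if np.issubdtype(self.values.dtype, np.floating):
            mask |= np.isnan(self.values)
        return mask

    def aligned_with(self, other: "RasterGrid") -> bool:
        """True iff shape, cell size and origin all match."""
        return (
            self.shape == other.shape
            and self.cell_size == other.cell_size
            and self.origin == other.origin
        )

    def copy(self, values: np.ndarray | None = None) -> "RasterGrid":
        return replace(self, values=self.values.copy() if values is None else values)

    # -- world <-> array coordinates -------------------------------------
    def cell_center(self, row, col):
        """World ``(x, y)`` of the centre of cell ``(row, col)``."""
        row = np.asarray(row)
        col = np.asarray(col)
        x = self.origin[0] + (col + 0.5) * self.cell_size
        y = self.origin[1] + (self.nrows - row - 0.5) * self.cell_size
        return x, y

    def world_to_cell(self, x: float, y: float) -> tuple[int, int]:
        col = int(np.floor((x - self.origin[0]) / self.cell_size))
        row = self.nrows - 1 - int(np.floor((y - self.origin[1]) / self.cell_size))
        return row, col

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """``(xmin, ymin, xmax, ymax)`` of the grid extent."""
        x0, y0 = self.origin
        return (x0, y0, x0 + self.ncols * self.cell_size, y0 + self.nrows * self.cell_size)


class ReclassTable:
    """Mapping from land-use category code to a strictly positive value.

    Used both for resistance assignment (category -> dispersal resistance)
    and any other categorical recoding. Loadable from a two-column CSV
    ``category,resistance``.
    """

    def __init__(self, mapping: dict[int, float]):
        self.mapping = {int(k): float(v) for k, v in mapping.items()}
        for k, v in self.mapping.items():
            if not v > 0:
                raise ValueError(f"reclass value for category {k} must be > 0, got {v}")

    def __getitem__(self, code: int) -> float:
        return self.mapping[int(code)]

    def __contains__(self, code: int) -> bool:
        return int(code) in self.mapping

    def categories(self) -> list[int]:
        return sorted(self.mapping)

    @classmethod
    def from_csv(cls, path: str | Path) -> "ReclassTable":
        mapping: dict[int, float] = {}
        with open(path, newline="") as fh:
            for i, row in enumerate(csv.reader(fh)):
                if not row or row[0].strip().startswith("#"):
                    continue
                if i == 0 and not row[0].strip().lstrip("-").isdigit():
                    continue  # header line
                mapping[int(row[0])] = float(row[1])
        return cls(mapping)

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["category", "resistance"])
            for k in self.categories():
                w.writerow([k, repr(self.mapping[k])])


def reclassify(grid: RasterGrid, table: ReclassTable) -> RasterGrid:
    """Map every category cell through ``table``; nodata cells are preserved.

    Raises
    ------
    KeyError
        If the grid contains a category without a table entry.
    """
    mask = grid.nodata_mask()
    cats = np.unique(grid.values[~mask])
    missing = [int(c) for c in cats if int(c) not in table]
    if missing:
        raise KeyError(f"unmapped category {missing[0]}")
    out = np.full(grid.shape, float(grid.nodata), dtype=float)
    for c in cats:
        out[(grid.values == c) & ~mask] = table[int(c)]
    return RasterGrid(out, grid.cell_size, grid.origin, float(grid.nodata))


def resample(grid: RasterGrid, factor: int, method: str = "auto") -> RasterGrid:
    """Aggregate ``factor`` x ``factor`` blocks of cells into one.

    ``method`` is ``"nearest"`` (block-representative cell, used for
    categorical grids), ``"mean"`` (block mean ignoring nodata) or ``"auto"``
    (nearest for integer dtypes, mean otherwise). Rows/columns that do not
    fill a whole block are truncated at the bottom/right edge; the origin is
    shifted so the retained top-left block stays in place.
    """
    factor = int(factor)
    if factor < 1:
        raise ValueError(f"resample factor must be >= 1, got {factor}")
    if factor == 1:
        return grid.copy()
    if method == "auto":
        method = "nearest" if np.issubdtype(grid.values.dtype, np.integer) else "mean"
    nr, nc = grid.nrows // factor, grid.ncols // factor
    if nr == 0 or nc == 0:
        raise ValueError("resample factor larger than grid")
    v = grid.values[: nr * factor, : nc * factor]
    if method == "nearest":
        off = factor // 2
        out = v[off::factor, off::factor][:nr, :nc].copy()
    elif method == "mean":
        blocks = v.reshape(nr, factor, nc, factor).astype(float)
        nod = grid.nodata_mask()[: nr * factor, : nc * factor].reshape(nr, factor, nc, factor)
        valid = (~nod).sum(axis=(1, 3))
        s = np.where(nod, 0.0, blocks).sum(axis=(1, 3))
        with np.errstate(invalid="ignore"):
            out = np.where(valid > 0, s / np.maximum(valid, 1), float(grid.nodata))
    else:
        raise ValueError(f"unknown resample method {method!r}")
    # truncated bottom rows raise the lower-left corner
    new_origin = (
        grid.origin[0],
        grid.origin[1] + (grid.nrows - nr * factor) * grid.cell_size,
    )
    return RasterGrid(out, grid.cell_size * factor, new_origin, float(grid.nodata))


def mosaic_and_mask(tiles: list[RasterGrid], boundary: shapely.Geometry) -> RasterGrid:
    """Mosaic aligned tiles into one grid and mask cells outside ``boundary``.

    Tiles must share ``cell_size`` and sit on a common cell lattice. Where
    tiles overlap the **first** tile in the list wins. A cell survives the
    mask iff its centre is covered by the boundary polygon; everything else
    becomes nodata.
    """
    if not tiles:
        raise ValueError("no tiles to mosaic")
    cs = tiles[0].cell_size
    nodata = tiles[0].nodata
    for t in tiles[1:]:
        if t.cell_size != cs:
            raise ValueError(f"misaligned cell sizes: {cs} vs {t.cell_size}")
        dx = (t.origin[0] - tiles[0].origin[0]) / cs
        dy = (t.origin[1] - tiles[0].origin[1]) / cs
        if abs(dx - round(dx)) > 1e-9 or abs(dy - round(dy)) > 1e-9:
            raise ValueError("tiles are not on a common cell lattice")
    xmin = min(t.bounds[0] for t in tiles)
    ymin = min(t.bounds[1] for t in tiles)
    xmax = max(t.bounds[2] for t in tiles)
    ymax = max(t.bounds[3] for t in tiles)
    ncols = round((xmax - xmin) / cs)
    nrows = round((ymax - ymin) / cs)
    dtype = np.result_type(*(t.values.dtype for t in tiles))
    out = np.full((nrows, ncols), nodata, dtype=dtype)
    filled = np.zeros((nrows, ncols), dtype=bool)
    for t in tiles:
        c0 = round((t.bounds[0] - xmin) / cs)
        r0 = nrows - round((t.bounds[3] - ymin) / cs)
        sl = (slice(r0, r0 + t.nrows), slice(c0, c0 + t.ncols))
        take = ~filled[sl] & ~t.nodata_mask()
        out[sl] = np.where(take, t.values, out[sl])
        filled[sl] |= take
    grid = RasterGrid(out, cs, (xmin, ymin), float(nodata))
    rows, cols = np.meshgrid(np.arange(nrows), np.arange(ncols), indexing="ij")
    x, y = grid.cell_center(rows.ravel(), cols.ravel())
    inside = shapely.intersects(boundary, shapely.points(x, y)).reshape(nrows, ncols)
    grid.values[~inside] = nodata
    return grid


# ---------------------------------------------------------------------------
# I/O


def write_raster(grid: RasterGrid, path: str | Path) -> None:
    """Write a grid as GeoTIFF (``.tif``/``.tiff``) or ESRI ASCII (``.asc``/``.txt``)."""
    path = Path(path)
    ext = path.suffix.lower()
    if ext in (".tif", ".tiff"):
        _write_geotiff(grid, path)
    elif ext in (".asc", ".txt"):
        _write_ascii(grid, path)
    else:
        raise ValueError(f"unsupported raster extension {ext!r}")


def read_raster(path: str | Path) -> RasterGrid:
    path = Path(path)
    ext = path.suffix.lower()
    if ext in (".tif", ".tiff"):
        return _read_geotiff(path)
    if ext in (".asc", ".txt"):
        return _read_ascii(path)
    raise ValueError(f"unsupported raster extension {ext!r}")


def _write_geotiff(grid: RasterGrid, path: Path) -> None:
    cs = float(grid.cell_size)
    x0, y0 = grid.origin
    ytop = y0 + grid.nrows * cs
    extratags = [
        (_TAG_MODEL_PIXEL_SCALE, "d", 3, (cs, cs, 0.0)),
        (_TAG_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, float(x0), float(ytop), 0.0)),
        (_TAG_GDAL_NODATA, "s", 0, repr(float(grid.nodata))),
    ]
    tifffile.imwrite(path, grid.values, extratags=extratags)


def _read_geotiff(path: Path) -> RasterGrid:
    try:
        with tifffile.TiffFile(path) as tif:
            page = tif.pages[0]
            values = page.asarray()
            tags = page.tags
            scale = tags[_TAG_MODEL_PIXEL_SCALE].value if _TAG_MODEL_PIXEL_SCALE in tags else (1.0, 1.0, 0.0)
            tie = (
                tags[_TAG_MODEL_TIEPOINT].value
                if _TAG_MODEL_TIEPOINT in tags
                else (0, 0, 0, 0.0, float(values.shape[0]), 0.0)
            )
            nodata = float(tags[_TAG_GDAL_NODATA].value) if _TAG_GDAL_NODATA in tags else DEFAULT_NODATA
    except ValueError:
        raise
    except Exception as exc:  # malformed container
        raise ValueError(f"cannot read GeoTIFF {path}: {exc}") from exc
    if values.ndim != 2:
        raise ValueError(f"{path}: expected a single-band raster, got shape {values.shape}")
    cs = float(scale[0])
    xtop, ytop = float(tie[3]), float(tie[4])
    origin = (xtop, ytop - values.shape[0] * cs)
    return RasterGrid(values, cs, origin, nodata)


_ASCII_KEYS = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize")


def _write_ascii(grid: RasterGrid, path: Path) -> None:
    is_int = np.issubdtype(grid.values.dtype, np.integer)
    with open(path, "w") as fh:
        fh.write(f"NCOLS {grid.ncols}\n")
        fh.write(f"NROWS {grid.nrows}\n")
        fh.write(f"XLLCORNER {grid.origin[0]!r}\n")
        fh.write(f"YLLCORNER {grid.origin[1]!r}\n")
        fh.write(f"CELLSIZE {grid.cell_size!r}\n")
        nod = int(grid.nodata) if is_int else float(grid.nodata)
        fh.write(f"NODATA_VALUE {nod!r}\n")
        for row in grid.values:
            if is_int:
                fh.write(" ".join(str(int(v)) for v in row) + "\n")
            else:
                fh.write(" ".join(repr(float(v)) for v in row) + "\n")


def _read_ascii(path: Path) -> RasterGrid:
    header: dict[str, float] = {}
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    while i < len(lines):
        parts = lines[i].split()
        if len(parts) == 2 and parts[0].lower() in _ASCII_KEYS + ("nodata_value",):
            try:
                header[parts[0].lower()] = float(parts[1])
            except ValueError:
                raise ValueError(f"{path}: line {i + 1}: cannot parse header value {parts[1]!r}")
            i += 1
        else:
            break
    for key in _ASCII_KEYS:
        if key not in header:
            raise ValueError(f"{path}: line {i + 1}: missing required header field {key.upper()}")
    nrows, ncols = int(header["nrows"]), int(header["ncols"])
    try:
        values = np.loadtxt(lines[i:], ndmin=2)
    except ValueError as exc:
        raise ValueError(f"{path}: line {i + 1}: cannot parse data block: {exc}") from exc
    if values.shape != (nrows, ncols):
        raise ValueError(
            f"{path}: data block is {values.shape}, header promises ({nrows}, {ncols})"
        )
    nodata = header.get("nodata_value", DEFAULT_NODATA)
    if np.all(values == np.round(values)) and np.all(np.abs(values) < 2**53):
        as_int = values.astype(np.int64)
        if np.all(as_int == values):
            values = as_int
    return RasterGrid(
        values, header["cellsize"], (header["xllcorner"], header["yllcorner"]), nodata
    )
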