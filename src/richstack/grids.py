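"""Regular geographic grids and the ESRI ASCII raster format.

All grids in richstack are 2-D float64 arrays in row-major, north-up
orientation: row 0 is the northernmost row.  Invalid (nodata) cells are
represented internally as NaN; the nodata sentinel only exists on disk.
Coordinates are geographic degrees (lon/lat, WGS84); cells are addressed
half-open, ``[x, x + cell_size)`` in longitude and ``(y - cell_size, y]``
descending from the north-west origin, and points are mapped to the cell
containing them.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .exceptions import AlignmentError, FormatError

__all__ = [
    "GridMeta",
    "read_ascii_grid",
    "write_ascii_grid",
    "points_to_cells",
    "cell_centers",
    "grids_aligned",
    "require_aligned",
]


@dataclass(frozen=True)
class GridMeta:
    """Geometry and nodata convention shared by a set of aligned grids.

    ``origin_x``/``origin_y`` give the *north-west corner* of the grid in
    degrees.  Cell (row, col) spans
    ``[origin_x + col*s, origin_x + (col+1)*s)`` in longitude and the
    matching half-open interval descending from ``origin_y`` in latitude,
    with ``s = cell_size``.
    """

    n_rows: int
    n_cols: int
    cell_size: float
    origin_x: float
    origin_y: float
    nodata: float = -9999.0
    crs_label: str = "GCS WGS84"

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and column")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    def matches(self, other: "GridMeta") -> bool:
        """Pixel alignment: same shape, cell size and origin (nodata and
        label may differ between files)."""
        return (
            self.shape == other.shape
            and np.isclose(self.cell_size, other.cell_size, rtol=0, atol=1e-9)
            and np.isclose(self.origin_x, other.origin_x, rtol=0, atol=1e-6 * self.cell_size)
            and np.isclose(self.origin_y, other.origin_y, rtol=0, atol=1e-6 * self.cell_size)
        )


def grids_aligned(meta_a: GridMeta, meta_b: GridMeta) -> bool:
    return meta_a.matches(meta_b)


def require_aligned(meta_a: GridMeta, meta_b: GridMeta, name: str = "layer") -> None:
    if not meta_a.matches(meta_b):
        raise AlignmentError(
            f"grid '{name}' is not aligned: expected {meta_a.shape} cell "
            f"{meta_a.cell_size} at ({meta_a.origin_x}, {meta_a.origin_y}), got "
            f"{meta_b.shape} cell {meta_b.cell_size} at "
            f"({meta_b.origin_x}, {meta_b.origin_y})"
        )


def points_to_cells(meta: GridMeta, lon: np.ndarray, lat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Map point coordinates to (row, col) indices; points outside the grid
    get out-of-range indices (callers test bounds themselves)."""
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    col = np.floor((lon - meta.origin_x) / meta.cell_size).astype(np.int64)
    row = np.floor((meta.origin_y - lat) / meta.cell_size).astype(np.int64)
    return row, col


def cell_centers(meta: GridMeta, row: np.ndarray, col: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Center coordinates (lon, lat) of the given cells."""
    row = np.asarray(row)
    col = np.asarray(col)
    lon = meta.origin_x + (col + 0.5) * meta.cell_size
    lat = meta.origin_y - (row + 0.5) * meta.cell_size
    return lon, lat


# --- ESRI ASCII grid ---------------------------------------------------------

_HEADER_KEYS = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize")


def read_ascii_grid(path) -> tuple[np.ndarray, GridMeta]:
    """Read an ESRI ASCII grid; nodata cells become NaN.

    Returns ``(values, meta)`` where ``values`` is a float64 array with
    row 0 the northernmost row (the on-disk order).
    """
    header: dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        while True:
            pos = fh.tell()
            line = fh.readline()
            if not line:
                raise FormatError(f"{path}: truncated header")
            parts = line.split()
            if len(parts) == 2 and parts[0].lower() in _HEADER_KEYS + ("nodata_value",):
                header[parts[0].lower()] = float(parts[1])
            else:
                fh.seek(pos)
                break
        missing = [k for k in _HEADER_KEYS if k not in header]
        if missing:
            raise FormatError(f"{path}: missing header field(s) {missing}")
        n_rows = int(header["nrows"])
        n_cols = int(header["ncols"])
        nodata = header.get("nodata_value", -9999.0)
        try:
            values = np.loadtxt(fh, dtype=float, ndmin=2)
        except ValueError as exc:
            raise FormatError(f"{path}: malformed data block: {exc}") from None
    if values.shape != (n_rows, n_cols):
        # loadtxt may flatten ragged-but-consistent streams; try a reshape
        if values.size == n_rows * n_cols:
            values = values.reshape(n_rows, n_cols)
        else:
            raise FormatError(
                f"{path}: data block has {values.size} values, header "
                f"declares {n_rows}x{n_cols}"
            )
    values[values == nodata] = np.nan
    meta = GridMeta(
        n_rows=n_rows,
        n_cols=n_cols,
        cell_size=header["cellsize"],
        origin_x=header["xllcorner"],
        origin_y=header["yllcorner"] + n_rows * header["cellsize"],
        nodata=nodata,
    )
    return values, meta


def write_ascii_grid(path, values: np.ndarray, meta: GridMeta, fmt: str = "%.6g") -> None:
    """Write a grid as ESRI ASCII, mapping NaN to the meta's nodata sentinel."""
    values = np.asarray(values, dtype=float)
    if values.shape != meta.shape:
        raise AlignmentError(
            f"array shape {values.shape} does not match meta {meta.shape}"
        )
    out = np.where(np.isnan(values), meta.nodata, values)
    yll = meta.origin_y - meta.n_rows * meta.cell_size
    with open(path, "w") as fh:
        fh.write(f"ncols {meta.n_cols}\n")
        fh.write(f"nrows {meta.n_rows}\n")
        fh.write(f"xllcorner {meta.origin_x:.10g}\n")
        fh.write(f"yllcorner {yll:.10g}\n")
        fh.write(f"cellsize {meta.cell_size:.10g}\n")
        fh.write(f"NODATA_value {meta.nodata:.10g}\n")
        np.savetxt(fh, out, fmt=fmt)


def with_nodata(meta: GridMeta, nodata: float) -> GridMeta:
    return replace(meta, nodata=nodata)
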