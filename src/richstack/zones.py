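"""Zonal schemes (ecoregions, elevation bands) and zonal change statistics.

Elevation bands come in two flavours: *equal interval* (fixed elevation
step, wildly varying areas when the DEM is right-skewed) and *equal area*
(equal pixel counts, varying elevation spans — the highest band can cover
most of the elevation range while the lowest covers almost none).  Change
maps are summarized per zone as mean / SD / min / max, with an
area-normalized mean (zone total change per km^2) for comparisons between
zones of different sizes.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import AlignmentError, InputError

EARTH_RADIUS_KM = 6371.0


@dataclass
class ZoneMap:
    """Integer zone labels over a grid plus a per-zone summary table."""

    labels: np.ndarray  # float grid; NaN = invalid, else integer label
    table: pd.DataFrame  # label, name, n_pixels (+ min/max elevation for bands)
    scheme: str


def _band_table(dem: np.ndarray, labels: np.ndarray, n_bands: int) -> pd.DataFrame:
    rows = []
    for b in range(1, n_bands + 1):
        sel = labels == b
        vals = dem[sel]
        rows.append(
            {
                "label": b,
                "name": f"band_{b}",
                "n_pixels": int(sel.sum()),
                "min_elev": float(vals.min()) if vals.size else float("nan"),
                "max_elev": float(vals.max()) if vals.size else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def equal_interval_bands(dem: np.ndarray, n_bands: int = 7, interval: float | None = None) -> ZoneMap:
    """Bands of equal elevation step over the DEM's valid range.

    The step defaults to ``(max - min) / n_bands``; an explicit ``interval``
    (e.g. a published round figure) overrides it.  Band ``i`` covers
    ``[min + (i-1)*step, min + i*step)`` with the top band closed at the
    maximum; labels ascend with elevation from 1.
    """
    valid = np.isfinite(dem)
    vals = dem[valid]
    if vals.size == 0 or vals.min() == vals.max():
        raise InputError("DEM is constant or empty; cannot build interval bands")
    lo, hi = float(vals.min()), float(vals.max())
    step = (hi - lo) / n_bands if interval is None else float(interval)
    labels = np.full(dem.shape, np.nan)
    idx = np.floor((dem[valid] - lo) / step).astype(int)
    idx = np.clip(idx, 0, n_bands - 1)  # top edge closed; override may overshoot
    labels[valid] = idx + 1
    return ZoneMap(labels=labels, table=_band_table(dem, labels, n_bands), scheme="equal_interval")


def equal_area_bands(dem: np.ndarray, n_bands: int = 7) -> ZoneMap:
    """Bands of (near-)equal pixel count, ascending in elevation.

    Valid pixels are ranked by elevation (ties by row-major position, via a
    stable sort) and split into contiguous rank groups whose sizes differ
    by at most one, the remainder going to the lowest bands.
    """
    valid = np.isfinite(dem)
    n = int(valid.sum())
    if n < n_bands:
        raise InputError(f"{n} valid pixels cannot form {n_bands} bands")
    flat_idx = np.flatnonzero(valid.ravel())
    order = np.argsort(dem.ravel()[flat_idx], kind="stable")
    base, rem = divmod(n, n_bands)
    sizes = np.full(n_bands, base)
    sizes[:rem] += 1
    band_of_rank = np.repeat(np.arange(1, n_bands + 1), sizes)
    labels = np.full(dem.size, np.nan)
    labels[flat_idx[order]] = band_of_rank
    labels = labels.reshape(dem.shape)
    return ZoneMap(labels=labels, table=_band_table(dem, labels, n_bands), scheme="equal_area")


def ecoregion_zones(label_grid: np.ndarray, names: dict[int, str] | None = None,
                    exclude: tuple[int, ...] = ()) -> ZoneMap:
    """Wrap an ecoregion label raster as a ZoneMap.

    ``exclude`` drops labels from the summary table (e.g. an ecoregion kept
    on the map for completeness but left out of reporting); their pixels
    remain labelled on the grid.
    """
    valid = np.isfinite(label_grid)
    labs = np.unique(label_grid[valid]).astype(int)
    rows = [
        {
            "label": int(b),
            "name": (names or {}).get(int(b), f"ecoregion_{int(b)}"),
            "n_pixels": int((label_grid == b).sum()),
        }
        for b in labs
        if int(b) not in exclude
    ]
    return ZoneMap(labels=label_grid.astype(float), table=pd.DataFrame(rows), scheme="ecoregion")


def band_range_share(band_min: float, band_max: float, dem_min: float, dem_max: float) -> float:
    """Percentage of the DEM's total elevation range a band spans."""
    if dem_max <= dem_min:
        raise InputError("degenerate elevation range")
    return 100.0 * (band_max - band_min) / (dem_max - dem_min)


def cell_area_grid(meta, per_cell_km2: float | None = None, cos_lat: bool = False) -> np.ndarray:
    """Per-pixel cell area in km^2 for a geographic grid.

    By default every cell gets the nominal area of a ``cell_size``-degree
    square at the equator; ``cos_lat=True`` scales each row by the cosine
    of its center latitude.
    """
    deg_km = 2 * np.pi * EARTH_RADIUS_KM / 360.0
    base = (meta.cell_size * deg_km) ** 2 if per_cell_km2 is None else per_cell_km2
    areas = np.full(meta.shape, float(base))
    if cos_lat:
        lats = meta.origin_y - (np.arange(meta.n_rows) + 0.5) * meta.cell_size
        areas *= np.cos(np.radians(lats))[:, None]
    return areas


def zonal_change_stats(change: np.ndarray, zones: ZoneMap, cell_area_km2=1.0) -> pd.DataFrame:
    """Per-zone summary of a change map.

    Columns: label, name, n_pixels (valid change pixels), area_km2, mean,
    sd (sample, ddof=1), min, max, and ``mean_per_km2`` = zone total change
    divided by zone area.  Zones without valid pixels keep their row with
    NaN statistics.  ``cell_area_km2`` may be a scalar or a per-pixel grid.
    """
    if change.shape != zones.labels.shape:
        raise AlignmentError("change map and zone map have mismatched shapes")
    area = (
        np.full(change.shape, float(cell_area_km2))
        if np.isscalar(cell_area_km2)
        else np.asarray(cell_area_km2, dtype=float)
    )
    rows = []
    for _, zrow in zones.table.iterrows():
        b = zrow["label"]
        sel = (zones.labels == b) & np.isfinite(change)
        vals = change[sel]
        a = float(area[sel].sum())
        if vals.size:
            total = float(vals.sum())
            rows.append(
                {
                    "label": b,
                    "name": zrow["name"],
                    "n_pixels": int(vals.size),
                    "area_km2": a,
                    "mean": float(vals.mean()),
                    "sd": float(vals.std(ddof=1)) if vals.size > 1 else float("nan"),
                    "min": float(vals.min()),
                    "max": float(vals.max()),
                    "mean_per_km2": total / a if a > 0 else float("nan"),
                }
            )
        else:
            rows.append(
                {
                    "label": b,
                    "name": zrow["name"],
                    "n_pixels": 0,
                    "area_km2": 0.0,
                    "mean": float("nan"),
                    "sd": float("nan"),
                    "min": float("nan"),
                    "max": float("nan"),
                    "mean_per_km2": float("nan"),
                }
            )
    return pd.DataFrame(rows)
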