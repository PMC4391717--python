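"""Occurrence filtering, genus aggregation, background sampling and SWD
assembly.

The filter chain mirrors standard presence-record hygiene for ~1 km
presence-background modelling: per-taxon deduplication at the grid-cell
level, restriction to the land mask, a collection-year cutoff, an elevation
ceiling read off the DEM, and removal of taxa left with too few records to
support a model.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import CapacityError, ConfigurationError
from .grids import cell_centers, points_to_cells
from .io import BACKGROUND_LABEL, EnvStack

log = logging.getLogger(__name__)


@dataclass
class FilterReport:
    """Record counts surviving each stage of the occurrence filter chain."""

    n_input: int = 0
    n_after_dedup: int = 0
    n_after_mask: int = 0
    n_after_date: int = 0
    n_after_elevation: int = 0
    taxa_retained: int = 0
    taxa_dropped_low_n: int = 0


def _attach_cells(occ: pd.DataFrame, stack: EnvStack) -> pd.DataFrame:
    occ = occ.copy()
    row, col = points_to_cells(stack.meta, occ["lon"].to_numpy(), occ["lat"].to_numpy())
    occ["_row"], occ["_col"] = row, col
    return occ


def filter_occurrences(
    occ: pd.DataFrame,
    stack: EnvStack,
    dem: np.ndarray,
    min_records: int = 11,
    min_year: int = 1981,
    max_elev: float = 2876.0,
) -> tuple[pd.DataFrame, FilterReport]:
    """Apply the four record-level filters and the minimum-record rule.

    Order: per-taxon per-cell deduplication (first record in input order
    kept) -> land-mask membership -> ``year >= min_year`` ->
    DEM elevation strictly below ``max_elev`` -> taxa with fewer than
    ``min_records`` surviving records dropped entirely.  The record's own
    elevation field is informational; the filter reads the DEM at the
    record's cell.
    """
    if dem.shape != stack.meta.shape:
        raise ConfigurationError("DEM does not conform to the stack grid")
    report = FilterReport(n_input=len(occ))
    if len(occ) == 0:
        return occ.copy(), report
    work = _attach_cells(occ, stack)
    n_taxa_in = work["taxon"].nunique()

    work = work.drop_duplicates(subset=["taxon", "_row", "_col"], keep="first")
    report.n_after_dedup = len(work)

    inb = (
        (work["_row"] >= 0)
        & (work["_row"] < stack.meta.n_rows)
        & (work["_col"] >= 0)
        & (work["_col"] < stack.meta.n_cols)
    )
    work = work[inb]
    on_land = stack.land_mask[work["_row"].to_numpy(), work["_col"].to_numpy()]
    work = work[on_land]
    report.n_after_mask = len(work)

    work = work[work["year"] >= min_year]
    report.n_after_date = len(work)

    cell_elev = dem[work["_row"].to_numpy(), work["_col"].to_numpy()]
    work = work[np.isfinite(cell_elev) & (cell_elev < max_elev)]
    report.n_after_elevation = len(work)

    counts = work["taxon"].value_counts()
    keep_taxa = counts.index[counts >= min_records]
    report.taxa_retained = len(keep_taxa)
    report.taxa_dropped_low_n = n_taxa_in - len(keep_taxa)
    out = work[work["taxon"].isin(keep_taxa)]
    return out.drop(columns=["_row", "_col"]).reset_index(drop=True), report


def aggregate_to_genus(occ: pd.DataFrame, meta=None) -> pd.DataFrame:
    """Pool species records into genus records.

    The genus is the first epithet of the binomial taxon name; pooled
    records are re-deduplicated per genus per grid cell (or per exact
    coordinate when no grid ``meta`` is given).  Non-binomial names are kept
    unchanged with a logged warning.
    """
    occ = occ.copy()
    parts = occ["taxon"].str.split()
    non_binomial = parts.str.len() < 2
    if non_binomial.any():
        log.warning(
            "%d record(s) with non-binomial names kept under their full name",
            int(non_binomial.sum()),
        )
    occ["taxon"] = np.where(non_binomial, occ["taxon"], parts.str[0])
    occ["level"] = "genus"
    if meta is not None:
        row, col = points_to_cells(meta, occ["lon"].to_numpy(), occ["lat"].to_numpy())
        occ["_row"], occ["_col"] = row, col
        occ = occ.drop_duplicates(subset=["taxon", "_row", "_col"], keep="first")
        occ = occ.drop(columns=["_row", "_col"])
    else:
        occ = occ.drop_duplicates(subset=["taxon", "lon", "lat"], keep="first")
    return occ.reset_index(drop=True)


def sample_background(stack: EnvStack, n: int, seed: int) -> pd.DataFrame:
    """Draw ``n`` distinct background cells uniformly from the land mask.

    Returns a DataFrame with columns lon, lat, row, col (cell centers);
    deterministic given ``seed``.
    """
    rows, cols = np.nonzero(stack.land_mask)
    m = rows.size
    if n > m:
        raise CapacityError(f"requested {n} background points from {m} land cells")
    rng = np.random.default_rng(seed)
    idx = rng.choice(m, size=n, replace=False)
    rows, cols = rows[idx], cols[idx]
    lon, lat = cell_centers(stack.meta, rows, cols)
    return pd.DataFrame({"lon": lon, "lat": lat, "row": rows, "col": cols})


def build_swd(
    occ: pd.DataFrame,
    background: pd.DataFrame,
    stack: EnvStack,
    layer_subset=None,
) -> pd.DataFrame:
    """Assemble an SWD table from presences and background points.

    One row per presence record and per background point, with covariate
    values from ``layer_subset`` (default: all stack layers) extracted at
    the point's cell.  Points on invalid cells are dropped with a logged
    count.
    """
    names = stack.layer_names if layer_subset is None else list(layer_subset)
    unknown = [n for n in names if n not in stack.layers]
    if unknown:
        raise ConfigurationError(f"unknown layer(s) in subset: {unknown}")

    frames = []
    for df, label_col in ((occ, "taxon"), (background, None)):
        if len(df) == 0:
            continue
        if "row" in df.columns and "col" in df.columns:
            row = df["row"].to_numpy()
            col = df["col"].to_numpy()
        else:
            row, col = points_to_cells(stack.meta, df["lon"].to_numpy(), df["lat"].to_numpy())
        inb = (
            (row >= 0)
            & (row < stack.meta.n_rows)
            & (col >= 0)
            & (col < stack.meta.n_cols)
        )
        valid = inb.copy()
        valid[inb] = stack.land_mask[row[inb], col[inb]]
        n_drop = int((~valid).sum())
        if n_drop:
            log.warning("build_swd: dropped %d point(s) on invalid cells", n_drop)
        covs = stack.values_at(row[valid], col[valid], names)
        labels = (
            df.loc[valid, label_col].to_numpy()
            if label_col
            else np.full(int(valid.sum()), BACKGROUND_LABEL, dtype=object)
        )
        part = pd.DataFrame(
            {
                "species": labels,
                "longitude": df.loc[valid, "lon"].to_numpy(),
                "latitude": df.loc[valid, "lat"].to_numpy(),
            }
        )
        frames.append(pd.concat([part, covs.reset_index(drop=True)], axis=1))
    if not frames:
        return pd.DataFrame(columns=["species", "longitude", "latitude", *names])
    return pd.concat(frames, ignore_index=True)
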