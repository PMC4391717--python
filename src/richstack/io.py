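"""Tabular and stacked-raster I/O: occurrence CSVs, environmental stacks
and the SWD (species-with-data) CSV layout.

Occurrence tables and SWD tables are plain :class:`pandas.DataFrame` objects
with documented column sets; environmental stacks are an
:class:`EnvStack` of named, pixel-aligned grids sharing one
:class:`~richstack.grids.GridMeta`.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import AlignmentError, FormatError
from .grids import GridMeta, read_ascii_grid, require_aligned

log = logging.getLogger(__name__)

#: required columns of an occurrence table
OCC_COLUMNS = ("taxon", "level", "lon", "lat", "year", "elevation")

#: the label used for background rows in SWD tables
BACKGROUND_LABEL = "background"

#: leading (non-covariate) columns of an SWD table
SWD_KEY_COLUMNS = ("species", "longitude", "latitude")

#: the nine climate covariates, in canonical order
CLIMATE_LAYERS = (
    "temp_mean",
    "temp_min",
    "temp_max",
    "prec_mean",
    "prec_min",
    "prec_max",
    "water_balance",
    "months_pos_wb",
    "evapotranspiration",
)

#: fractional land-cover covariates that enter the models (bare soil never does)
LANDCOVER_LAYERS = ("tree_pct", "herb_pct")

ALL_LAYERS = CLIMATE_LAYERS + LANDCOVER_LAYERS


@dataclass
class EnvStack:
    """Aligned multi-layer environmental grid.

    Every layer conforms to ``meta``; cells outside ``land_mask`` are NaN in
    every layer.  ``epoch`` tags the stack as describing recent or future
    conditions.
    """

    meta: GridMeta
    layers: dict[str, np.ndarray]
    land_mask: np.ndarray
    epoch: str = "recent"

    def __post_init__(self) -> None:
        for name, arr in self.layers.items():
            if arr.shape != self.meta.shape:
                raise AlignmentError(
                    f"layer '{name}' shape {arr.shape} != meta {self.meta.shape}"
                )
        if self.land_mask.shape != self.meta.shape:
            raise AlignmentError("land_mask shape does not match meta")

    @property
    def layer_names(self) -> list[str]:
        return list(self.layers)

    @property
    def n_land(self) -> int:
        return int(self.land_mask.sum())

    def subset(self, names) -> "EnvStack":
        """A view-stack restricted to the named layers (grids shared)."""
        missing = [n for n in names if n not in self.layers]
        if missing:
            raise KeyError(f"unknown layer(s): {missing}")
        return EnvStack(
            meta=self.meta,
            layers={n: self.layers[n] for n in names},
            land_mask=self.land_mask,
            epoch=self.epoch,
        )

    def replace_layers(self, new_layers: dict[str, np.ndarray], epoch: str | None = None) -> "EnvStack":
        layers = dict(self.layers)
        for name, arr in new_layers.items():
            if arr.shape != self.meta.shape:
                raise AlignmentError(f"layer '{name}' shape mismatch")
            layers[name] = arr
        return EnvStack(
            meta=self.meta,
            layers=layers,
            land_mask=self.land_mask,
            epoch=self.epoch if epoch is None else epoch,
        )

    def values_at(self, rows: np.ndarray, cols: np.ndarray, names=None) -> pd.DataFrame:
        """Covariate values at the given cells, one column per layer."""
        names = self.layer_names if names is None else list(names)
        data = {n: self.layers[n][rows, cols] for n in names}
        return pd.DataFrame(data)


@dataclass
class ParseReport:
    """Outcome of parsing an occurrence CSV."""

    n_rows: int = 0
    n_parsed: int = 0
    n_skipped: int = 0
    skipped_rows: list = field(default_factory=list)


def load_occurrences(path, level: str = "species") -> tuple[pd.DataFrame, ParseReport]:
    """Read an occurrence CSV with columns taxon, lon, lat, year, elevation.

    Rows whose numeric fields do not parse are skipped and counted in the
    returned :class:`ParseReport`; a missing required column raises
    :class:`FormatError`.
    """
    if level not in ("species", "genus"):
        raise ValueError(f"level must be 'species' or 'genus', got {level!r}")
    raw = pd.read_csv(path, dtype=str)
    raw.columns = [c.strip().lower() for c in raw.columns]
    required = ("taxon", "lon", "lat", "year", "elevation")
    for col in required:
        if col not in raw.columns:
            raise FormatError(f"occurrence file {path} is missing column '{col}'")
    report = ParseReport(n_rows=len(raw))
    num = (
        raw[["lon", "lat", "year", "elevation"]]
        .apply(pd.to_numeric, errors="coerce")
        .astype(float)
        .replace([np.inf, -np.inf], np.nan)
    )
    ok = num[["lon", "lat", "year"]].notna().all(axis=1) & raw["taxon"].notna()
    report.n_skipped = int((~ok).sum())
    report.skipped_rows = list(raw.index[~ok])
    report.n_parsed = int(ok.sum())
    out = pd.DataFrame(
        {
            "taxon": raw.loc[ok, "taxon"].str.strip(),
            "level": level,
            "lon": num.loc[ok, "lon"].astype(float),
            "lat": num.loc[ok, "lat"].astype(float),
            "year": num.loc[ok, "year"].astype(int),
            "elevation": num.loc[ok, "elevation"].astype(float),
        }
    ).reset_index(drop=True)
    if report.n_skipped:
        log.warning("%s: skipped %d malformed row(s)", path, report.n_skipped)
    return out, report


def load_env_stack(paths: dict[str, str], mask_path=None, epoch: str = "recent") -> EnvStack:
    """Assemble an :class:`EnvStack` from per-layer ESRI ASCII rasters.

    All rasters must be pixel-aligned; cells that are nodata in *any* layer
    (or outside the optional mask raster, where mask <= 0) are removed from
    the land mask and set to NaN in every layer.
    """
    if not paths:
        raise ValueError("no layers given")
    layers: dict[str, np.ndarray] = {}
    meta: GridMeta | None = None
    for name, p in paths.items():
        arr, m = read_ascii_grid(p)
        if meta is None:
            meta = m
        else:
            require_aligned(meta, m, name)
        layers[name] = arr
    assert meta is not None
    mask = np.ones(meta.shape, dtype=bool)
    if mask_path is not None:
        marr, mmeta = read_ascii_grid(mask_path)
        require_aligned(meta, mmeta, "mask")
        mask &= np.nan_to_num(marr, nan=0.0) > 0
    for arr in layers.values():
        mask &= np.isfinite(arr)
    for arr in layers.values():
        arr[~mask] = np.nan
    return EnvStack(meta=meta, layers=layers, land_mask=mask, epoch=epoch)


# --- SWD ---------------------------------------------------------------------


def write_swd(table: pd.DataFrame, path, precision: int = 6) -> None:
    """Write an SWD table (``species,longitude,latitude,<covariates...>``)."""
    for col in SWD_KEY_COLUMNS:
        if col not in table.columns:
            raise FormatError(f"SWD table lacks required column '{col}'")
    table.to_csv(path, index=False, float_format=f"%.{precision}g")


def read_swd(path) -> pd.DataFrame:
    """Read an SWD CSV; raises :class:`FormatError` on ragged rows."""
    try:
        table = pd.read_csv(path)
    except pd.errors.ParserError as exc:
        raise FormatError(f"{path}: {exc}") from None
    cols = list(table.columns)
    if cols[:3] != list(SWD_KEY_COLUMNS):
        raise FormatError(
            f"{path}: SWD header must start with {','.join(SWD_KEY_COLUMNS)}"
        )
    covs = cols[3:]
    bad = table[covs].isna().any(axis=1)
    if bad.any():
        raise FormatError(
            f"{path}: row {int(table.index[bad][0]) + 2} has missing covariate values"
        )
    return table


def swd_covariates(table: pd.DataFrame) -> list[str]:
    """The covariate (layer) columns of an SWD table, in order."""
    return [c for c in table.columns if c not in SWD_KEY_COLUMNS]


def swd_split(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split an SWD table into (presence rows, background rows)."""
    is_bg = table["species"] == BACKGROUND_LABEL
    return table[~is_bg], table[is_bg]
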