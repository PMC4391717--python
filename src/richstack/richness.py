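"""Stacked-SDM richness maps, change maps and the scenario factorial.

Per-taxon suitability maps are binarized at their chosen thresholds and
summed into a richness map per epoch; differencing future minus recent
gives a per-pixel richness-change map.  The full design crosses three
environmental-change scenarios (climate only, land cover only, combined),
three threshold rules and two taxonomic levels (species, genus) under
recent and future conditions — 36 richness maps and 18 change maps on the
defaults.  For each scenario x level, the run whose mean richness change is
closest to zero is the conservative run carried into zonal analysis.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import AlignmentError, InputError
from .io import ALL_LAYERS, CLIMATE_LAYERS, LANDCOVER_LAYERS, EnvStack, swd_split
from .maxent import SuitabilityGrid, build_features, fit_maxent, predict
from .evaluation import canonical_rule, select_threshold
from .occurrences import build_swd, sample_background

log = logging.getLogger(__name__)

SCENARIO_LAYERS = {
    "climate_only": CLIMATE_LAYERS,
    "landcover_only": LANDCOVER_LAYERS,
    "combined": ALL_LAYERS,
}


@dataclass
class ScenarioSpec:
    """One environmental-change scenario: the layer subset models see, and
    the recent/future stacks to train on and project onto."""

    id: str
    recent: EnvStack
    future: EnvStack
    layer_subset: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.layer_subset is None:
            if self.id not in SCENARIO_LAYERS:
                raise InputError(
                    f"scenario {self.id!r} needs an explicit layer_subset"
                )
            self.layer_subset = tuple(SCENARIO_LAYERS[self.id])


def _values(grid) -> np.ndarray:
    return grid.values if isinstance(grid, SuitabilityGrid) else np.asarray(grid)


def stack_richness(suitability: list, thresholds: list[float], shape=None) -> np.ndarray:
    """Per-pixel count of taxa whose suitability meets their threshold.

    ``score >= threshold`` counts as present; pixels that are nodata (NaN)
    in the suitability grids stay NaN.  An empty taxon list yields an
    all-zero map (``shape`` required then).
    """
    if len(suitability) != len(thresholds):
        raise InputError("one threshold per suitability grid is required")
    if not suitability:
        if shape is None:
            raise InputError("shape required for an empty taxon list")
        return np.zeros(shape)
    first = _values(suitability[0])
    richness = np.zeros(first.shape)
    invalid = np.zeros(first.shape, dtype=bool)
    for grid, thr in zip(suitability, thresholds):
        vals = _values(grid)
        if vals.shape != first.shape:
            raise AlignmentError("suitability grids have mismatched shapes")
        invalid |= np.isnan(vals)
        richness += np.where(np.isnan(vals), 0, vals >= thr)
    richness[invalid] = np.nan
    return richness


def change_map(recent: np.ndarray, future: np.ndarray) -> np.ndarray:
    """Future minus recent richness; nodata in either propagates."""
    recent = _values(recent)
    future = _values(future)
    if recent.shape != future.shape:
        raise AlignmentError("richness maps have mismatched shapes")
    return future - recent


@dataclass
class ChangeHistogram:
    """Integer-binned frequency distribution of pixel-level change."""

    counts: pd.Series  # index: bin lower edge; value: pixel count
    n_valid: int
    min: float
    mean: float
    max: float


def change_histogram(change: np.ndarray, bin_width: int = 1) -> ChangeHistogram:
    """Frequency distribution of per-pixel change plus min/mean/max.

    Bins are ``[i*w, (i+1)*w)`` for integer ``i`` and ``w = bin_width``;
    counts sum to the number of valid (non-NaN) pixels.
    """
    if bin_width < 1:
        raise InputError("bin_width must be >= 1")
    vals = np.asarray(change)[np.isfinite(np.asarray(change))]
    if vals.size == 0:
        return ChangeHistogram(
            counts=pd.Series(dtype=int), n_valid=0,
            min=float("nan"), mean=float("nan"), max=float("nan"),
        )
    binned = np.floor_divide(vals, bin_width).astype(int) * bin_width
    counts = pd.Series(binned).value_counts().sort_index()
    return ChangeHistogram(
        counts=counts,
        n_valid=int(vals.size),
        min=float(vals.min()),
        mean=float(vals.mean()),
        max=float(vals.max()),
    )


def select_run(candidates: list[tuple[str, float]]) -> str:
    """The threshold rule whose mean richness change is closest to zero.

    ``candidates`` pairs rule ids with mean change; ties break in
    T1, T2, T3 order.
    """
    if not candidates:
        raise InputError("no candidate runs")
    order = {canonical_rule(r): i for i, r in enumerate(("T1", "T2", "T3"))}
    best = min(candidates, key=lambda c: (abs(c[1]), order[canonical_rule(c[0])]))
    return best[0]


@dataclass
class FactorialResult:
    """All maps and provenance from one factorial run."""

    richness: dict[tuple, np.ndarray] = field(default_factory=dict)
    #: keys (scenario, rule, level, epoch)
    change: dict[tuple, np.ndarray] = field(default_factory=dict)
    #: keys (scenario, rule, level)
    thresholds: dict[tuple, dict[str, float]] = field(default_factory=dict)
    #: keys (scenario, rule, level) -> taxon -> threshold
    manifest: pd.DataFrame = field(default_factory=pd.DataFrame)
    errors: list[dict] = field(default_factory=list)

    def mean_changes(self, scenario: str, level: str) -> list[tuple[str, float]]:
        out = []
        for (s, rule, lv), chg in self.change.items():
            if s == scenario and lv == level:
                out.append((rule, float(np.nanmean(chg))))
        return out


def run_factorial(
    scenarios: list[ScenarioSpec],
    occurrences: dict[str, pd.DataFrame],
    rules=("T1", "T2", "T3"),
    n_background: int = 10_000,
    seed: int = 0,
    beta0: float = 0.25,
    classes=("linear", "quadratic"),
) -> FactorialResult:
    """Run the full scenario x rule x level factorial.

    ``occurrences`` maps taxonomic level ("species", "genus") to a filtered
    occurrence table.  Per scenario x level, each taxon's model is fitted
    once on the scenario's recent layers and projected to both epochs; the
    three rules then threshold the same fitted models.  One background
    sample (capped at the number of land cells) is shared by all taxa.
    A failing pipeline cell is logged into ``result.errors`` and the rest
    of the factorial continues.
    """
    rules = [canonical_rule(r) for r in rules]
    result = FactorialResult()
    rows = []
    for scen in scenarios:
        n_bg = min(n_background, scen.recent.n_land)
        background = sample_background(scen.recent, n_bg, seed)
        for level, occ in occurrences.items():
            taxa = sorted(occ["taxon"].unique())
            try:
                swd_all = build_swd(occ, background, scen.recent, scen.layer_subset)
            except Exception as exc:  # pragma: no cover - defensive
                log.error("scenario %s level %s failed: %s", scen.id, level, exc)
                result.errors.append(
                    {"scenario": scen.id, "level": level, "error": str(exc)}
                )
                continue
            _, bg_rows = swd_split(swd_all)
            fs = build_features(bg_rows, classes=classes)

            # accumulate binary maps per rule and epoch while fitting once
            rich = {
                (rule, epoch): np.zeros(scen.recent.meta.shape)
                for rule in rules
                for epoch in ("recent", "future")
            }
            invalid = {
                "recent": ~scen.recent.land_mask,
                "future": ~scen.future.land_mask,
            }
            thr_store: dict[str, dict[str, float]] = {r: {} for r in rules}
            for taxon in taxa:
                swd_t = swd_all[
                    (swd_all["species"] == taxon)
                    | (swd_all["species"] == "background")
                ]
                try:
                    model = fit_maxent(swd_t, fs, beta0=beta0)
                except Exception as exc:
                    log.error(
                        "fit failed for %s (%s, %s): %s", taxon, scen.id, level, exc
                    )
                    result.errors.append(
                        {
                            "scenario": scen.id,
                            "level": level,
                            "taxon": taxon,
                            "error": str(exc),
                        }
                    )
                    continue
                pres_t, _ = swd_split(swd_t)
                pres_scores = model.score_table(pres_t, scale="logistic")
                bg_scores = model.score_table(bg_rows, scale="logistic")
                grids = {
                    epoch: predict(
                        model,
                        stack.subset(scen.layer_subset),
                        scale="logistic",
                        taxon_id=taxon,
                        scenario_id=scen.id,
                    ).values
                    for epoch, stack in (
                        ("recent", scen.recent),
                        ("future", scen.future),
                    )
                }
                for rule in rules:
                    thr = select_threshold(pres_scores, bg_scores, rule).value
                    thr_store[rule][taxon] = thr
                    for epoch in ("recent", "future"):
                        rich[(rule, epoch)] += np.where(
                            np.isnan(grids[epoch]), 0, grids[epoch] >= thr
                        )
            for rule in rules:
                for epoch in ("recent", "future"):
                    arr = rich[(rule, epoch)]
                    arr[invalid[epoch]] = np.nan
                    result.richness[(scen.id, rule, level, epoch)] = arr
                    rows.append(
                        {
                            "map_type": "richness",
                            "scenario": scen.id,
                            "rule": rule,
                            "level": level,
                            "epoch": epoch,
                            "seed": seed,
                            "n_taxa": len(thr_store[rule]),
                        }
                    )
                chg = change_map(
                    result.richness[(scen.id, rule, level, "recent")],
                    result.richness[(scen.id, rule, level, "future")],
                )
                result.change[(scen.id, rule, level)] = chg
                result.thresholds[(scen.id, rule, level)] = thr_store[rule]
                rows.append(
                    {
                        "map_type": "change",
                        "scenario": scen.id,
                        "rule": rule,
                        "level": level,
                        "epoch": "future-recent",
                        "seed": seed,
                        "n_taxa": len(thr_store[rule]),
                    }
                )
    result.manifest = pd.DataFrame(rows)
    return result
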