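"""Seeded synthetic landscapes and virtual taxa with known suitability.

The generator emulates the data a stacked-SDM study consumes: nine smooth,
spatially autocorrelated climate-like covariate fields; fractional tree /
herb / bare cover summing to 100 per pixel; a right-skewed non-negative
DEM (few high cells, most of the area low); a categorical ecoregion map;
and a land mask with a small sea fraction.  Virtual taxa respond to scaled
covariates through a known logistic (linear + quadratic) suitability
function, so fitted models can be scored against exact ground truth, and
occurrence records are sampled with probability proportional to true
suitability.

Everything is deterministic given its seed.  Future conditions are built
by additive / multiplicative climate deltas (uniform warming with a
north-south gradient, an east-west precipitation shift, warming-driven
evapotranspiration) and by the deforestation projector for land cover, so
the three scenario semantics (climate only, land cover only, combined)
are exactly exercisable.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.special import expit

from .exceptions import AlignmentError, CapacityError
from .grids import GridMeta, cell_centers
from .io import ALL_LAYERS, EnvStack
from .landcover import DeforestationSchedule, LandCoverState, project_landcover
from .richness import ScenarioSpec

_GENUS_POOL = (
    "Aloea", "Vakona", "Tapia", "Ravena", "Hazomala", "Sakoa",
    "Voatavo", "Kininina", "Famata", "Hintsina",
)

# covariates grouped by construction-time correlation; a taxon's active
# covariates come from distinct families so its truth is identifiable
_COV_FAMILIES = (
    ("temp_mean", "temp_min", "temp_max"),
    ("prec_mean", "prec_min", "prec_max", "water_balance", "months_pos_wb"),
    ("evapotranspiration",),
    ("tree_pct", "herb_pct"),
)

# default study conditions for end-to-end runs
DEFAULT_ROWS = 100
DEFAULT_COLS = 100
DEFAULT_N_TAXA = 30
DEFAULT_N_PRESENCES = 200


@dataclass
class SyntheticLandscape:
    """A complete synthetic study region (recent epoch)."""

    stack: EnvStack  # 9 climate layers + tree_pct + herb_pct
    dem: np.ndarray
    bare_pct: np.ndarray
    ecoregions: np.ndarray  # labels 1..6, NaN off-mask
    seed: int

    @property
    def meta(self) -> GridMeta:
        return self.stack.meta


def _smooth_field(rng: np.random.Generator, shape, sigma: float) -> np.ndarray:
    """Standardized, spatially autocorrelated noise field."""
    f = gaussian_filter(rng.standard_normal(shape), sigma=sigma, mode="reflect")
    return (f - f.mean()) / f.std()


def gen_landscape(
    n_rows: int = DEFAULT_ROWS,
    n_cols: int = DEFAULT_COLS,
    seed: int = 42,
    smoothness: float = 6.0,
    sea_fraction: float = 0.06,
    dem_max: float = 2600.0,
) -> SyntheticLandscape:
    """Generate a seeded synthetic landscape.

    Each covariate is smoothed seeded noise plus a directional gradient,
    mapped into field-realistic units (temperatures in deg C, precipitation
    and water balance in mm, cover in percent).  The DEM is cubed from a
    smooth [0, 1] field, giving the right-skewed hypsometry of a mountain
    island: few high cells, most of the area low.  ``dem_max`` stays below
    the occurrence-filter elevation ceiling so that filter is non-binding
    unless a test raises it deliberately.
    """
    if n_rows < 10 or n_cols < 10:
        raise ValueError("landscape must be at least 10x10")
    rng = np.random.default_rng(seed)
    shape = (n_rows, n_cols)
    f = [_smooth_field(rng, shape, smoothness) for _ in range(14)]
    gy = np.linspace(0.0, 1.0, n_rows)[:, None] * np.ones(shape)  # north->south
    gx = np.ones(shape) * np.linspace(0.0, 1.0, n_cols)[None, :]  # west->east

    u = f[0] - f[0].min()
    u /= u.max()
    dem = dem_max * u**3

    temp_mean = 26.0 - 0.006 * dem - 2.0 * gy + 1.5 * f[1]
    temp_min = temp_mean - 6.0 + 0.8 * f[2]
    temp_max = temp_mean + 6.0 + 0.8 * f[3]
    prec_mean = np.clip(1100.0 + 600.0 * f[4] + 500.0 * gx, 50.0, None)
    prec_min = np.clip(0.05 * prec_mean + 15.0 * f[5], 0.0, None)
    prec_max = np.clip(0.25 * prec_mean + 40.0 * f[6], 10.0, None)
    evapo = np.clip(900.0 + 140.0 * f[7] + 30.0 * temp_mean / 26.0, 100.0, None)
    water_balance = prec_mean - evapo + 120.0 * f[8]
    months_pos_wb = np.clip(6.5 + 2.5 * f[9] + 2.0 * water_balance / 1500.0, 1.0, 12.0)

    tree = 90.0 * expit(1.2 * f[10] + 1.0 * (gx - 0.5))
    bare_frac = 0.02 + 0.20 * expit(f[11] + dem / 1500.0 - 1.0)
    bare = (100.0 - tree) * bare_frac
    herb = 100.0 - tree - bare

    sea_score = f[12] - 1.5 * ((gx - 0.5) ** 2 + (gy - 0.5) ** 2)
    mask = sea_score > np.quantile(sea_score, sea_fraction)

    layers = {
        "temp_mean": temp_mean,
        "temp_min": temp_min,
        "temp_max": temp_max,
        "prec_mean": prec_mean,
        "prec_min": prec_min,
        "prec_max": prec_max,
        "water_balance": water_balance,
        "months_pos_wb": months_pos_wb,
        "evapotranspiration": evapo,
        "tree_pct": tree,
        "herb_pct": herb,
    }
    for arr in layers.values():
        arr[~mask] = np.nan
    dem = dem.copy()
    dem[~mask] = np.nan
    bare = bare.copy()
    bare[~mask] = np.nan

    composite = f[13] + 1.6 * (dem / dem_max) + 0.8 * gy
    eco = np.full(shape, np.nan)
    edges = np.nanquantile(composite[mask], np.linspace(0, 1, 7)[1:-1])
    eco[mask] = np.digitize(composite[mask], edges) + 1.0

    meta = GridMeta(
        n_rows=n_rows,
        n_cols=n_cols,
        cell_size=1.0 / 120.0,  # 30 arc-seconds
        origin_x=44.0,
        origin_y=-12.0,
    )
    stack = EnvStack(meta=meta, layers=layers, land_mask=mask, epoch="recent")
    return SyntheticLandscape(stack=stack, dem=dem, bare_pct=bare, ecoregions=eco, seed=seed)


@dataclass
class VirtualTaxon:
    """A simulated taxon with a known logistic suitability function.

    Suitability is ``expit(alpha + sum_j beta_j z_j + sum_j gamma_j z_j^2)``
    on covariates affinely scaled by the generating landscape's valid-cell
    range; the true range is ``suitability >= 0.5``.
    """

    taxon_id: str
    alpha: float
    beta: dict[str, float] = field(default_factory=dict)
    gamma: dict[str, float] = field(default_factory=dict)
    scaling: dict[str, tuple[float, float]] = field(default_factory=dict)

    def suitability(self, stack: EnvStack) -> np.ndarray:
        """True suitability grid on any conforming stack (NaN off-mask)."""
        eta = np.full(stack.meta.shape, self.alpha)
        for cov, (lo, hi) in self.scaling.items():
            z = (stack.layers[cov] - lo) / (hi - lo)
            eta = eta + self.beta.get(cov, 0.0) * z + self.gamma.get(cov, 0.0) * z**2
        s = expit(eta)
        s[~stack.land_mask] = np.nan
        return s

    def true_range(self, stack: EnvStack) -> np.ndarray:
        """Boolean true-range grid (suitability >= 0.5); NaN propagates."""
        s = self.suitability(stack)
        out = np.where(np.isnan(s), np.nan, (s >= 0.5).astype(float))
        return out


def gen_virtual_taxa(
    landscape: SyntheticLandscape,
    n_taxa: int = DEFAULT_N_TAXA,
    seed: int = 1,
    effect_scale: float = 4.0,
    n_active: int = 3,
) -> list[VirtualTaxon]:
    """Draw virtual taxa with seeded coefficients and bounded prevalence.

    Each taxon responds to ``n_active`` covariates — drawn one each from
    distinct correlated covariate families (temperatures, precipitations,
    water balance, evapotranspiration, land cover), so its ground truth is
    identifiable rather than a near-cancelling mix of collinear layers —
    through a unimodal (Gaussian-niche style) response with an optimum drawn in
    [0.1, 0.9] of the scaled covariate range and a negative quadratic term,
    so every response curve peaks inside the observable range.  Because
    covariates are spatially correlated, the niche contrast a coefficient
    draw *realizes* over the landscape is unpredictable, so the
    coefficients are rescaled jointly to hit a drawn target for the
    realized logit span over valid cells: ``span ~ U(2, 3) * effect_scale``
    (8-12 logits at the default ``effect_scale=4``, so suitability traverses essentially the whole unit interval), which makes true
    suitability traverse essentially the whole (0, 1) interval — a
    well-defined niche with clearly suitable and clearly unsuitable
    habitat.  The intercept is then set so the true-range prevalence hits
    a target drawn uniformly in [0.1, 0.5]; taxa whose realized prevalence
    falls outside [0.02, 0.8] are redrawn.
    """
    rng = np.random.default_rng(seed)
    stack = landscape.stack
    covs = list(ALL_LAYERS)
    scaling = {}
    for cov in covs:
        vals = stack.layers[cov][stack.land_mask]
        scaling[cov] = (float(vals.min()), float(vals.max()))
    z = {
        cov: (stack.layers[cov][stack.land_mask] - lo) / (hi - lo)
        for cov, (lo, hi) in scaling.items()
    }
    taxa: list[VirtualTaxon] = []
    for i in range(n_taxa):
        for _attempt in range(50):
            fam_idx = rng.choice(len(_COV_FAMILIES), size=n_active, replace=False)
            active = [
                int(covs.index(_COV_FAMILIES[fi][rng.integers(len(_COV_FAMILIES[fi]))]))
                for fi in fam_idx
            ]
            beta: dict[str, float] = {}
            gamma: dict[str, float] = {}
            for j in active:
                m = float(rng.uniform(0.1, 0.9))
                depth = float(rng.uniform(1.0, 2.0))
                g = -depth / max(m, 1.0 - m) ** 2
                gamma[covs[j]] = g
                beta[covs[j]] = -2.0 * g * m
            eta0 = np.zeros(int(stack.land_mask.sum()))
            for cov in beta:
                eta0 += beta[cov] * z[cov] + gamma[cov] * z[cov] ** 2
            span_target = float(rng.uniform(2.0, 3.0)) * effect_scale
            c = span_target / float(eta0.max() - eta0.min())
            beta = {k: c * v for k, v in beta.items()}
            gamma = {k: c * v for k, v in gamma.items()}
            eta0 *= c
            target = float(rng.uniform(0.1, 0.5))
            alpha = float(-np.quantile(eta0, 1.0 - target))
            prevalence = float(np.mean(eta0 + alpha >= 0.0))
            if 0.02 <= prevalence <= 0.8:
                genus = _GENUS_POOL[i % len(_GENUS_POOL)]
                taxa.append(
                    VirtualTaxon(
                        taxon_id=f"{genus} virtualis{i + 1}",
                        alpha=alpha,
                        beta=beta,
                        gamma=gamma,
                        scaling={c: scaling[c] for c in beta},
                    )
                )
                break
        else:  # pragma: no cover - prevalence targeting makes this unreachable
            raise RuntimeError(f"could not generate taxon {i} within bounds")
    return taxa


def sample_occurrences(
    taxon: VirtualTaxon,
    landscape: SyntheticLandscape,
    n: int = DEFAULT_N_PRESENCES,
    seed: int = 0,
    year_range: tuple[int, int] = (1981, 2010),
) -> pd.DataFrame:
    """Sample presence records with probability proportional to suitability.

    Cells are drawn without replacement; records carry the cell-center
    coordinates, a uniform collection year in ``year_range`` and the DEM
    elevation of the cell.
    """
    stack = landscape.stack
    rows, cols = np.nonzero(stack.land_mask)
    if n > rows.size:
        raise CapacityError(f"requested {n} occurrences from {rows.size} valid cells")
    s = taxon.suitability(stack)[stack.land_mask]
    p = s / s.sum()
    rng = np.random.default_rng(seed)
    idx = rng.choice(rows.size, size=n, replace=False, p=p)
    lon, lat = cell_centers(stack.meta, rows[idx], cols[idx])
    years = rng.integers(year_range[0], year_range[1] + 1, size=n)
    elev = landscape.dem[rows[idx], cols[idx]]
    return pd.DataFrame(
        {
            "taxon": taxon.taxon_id,
            "level": "species",
            "lon": lon,
            "lat": lat,
            "year": years,
            "elevation": elev,
        }
    )


def make_future_climate(
    landscape: SyntheticLandscape,
    warming: float = 2.7,
    warming_gradient: float = 0.8,
    precip_shift: float = 0.1,
) -> dict[str, np.ndarray]:
    """Future climate layers: warming with a north-south gradient, an
    east-west precipitation shift, and warming-driven evapotranspiration.

    ``warming`` is the mean temperature increase (deg C, the level expected
    under a doubling of CO2); the gradient adds up to ``+/- warming_gradient``
    from north to south.  Precipitation scales by ``1 +/- precip_shift``
    from west to east; water balance and wet-month counts adjust
    consistently.
    """
    st = landscape.stack
    n_rows, n_cols = st.meta.shape
    gy = np.linspace(0.0, 1.0, n_rows)[:, None] * np.ones(st.meta.shape)
    gx = np.ones(st.meta.shape) * np.linspace(0.0, 1.0, n_cols)[None, :]
    dtemp = warming + warming_gradient * (gy - 0.5) * 2.0
    pfac = 1.0 + precip_shift * (gx - 0.5) * 2.0
    out = {}
    for name in ("temp_mean", "temp_min", "temp_max"):
        out[name] = st.layers[name] + dtemp
    for name in ("prec_mean", "prec_min", "prec_max"):
        out[name] = st.layers[name] * pfac
    et = st.layers["evapotranspiration"] * (1.0 + 0.03 * dtemp)
    out["evapotranspiration"] = et
    dwb = (out["prec_mean"] - st.layers["prec_mean"]) - (
        et - st.layers["evapotranspiration"]
    )
    out["water_balance"] = st.layers["water_balance"] + dwb
    out["months_pos_wb"] = np.clip(
        st.layers["months_pos_wb"] + dwb / 150.0, 1.0, 12.0
    )
    return out


def make_future_landcover(
    landscape: SyntheticLandscape,
    schedule: DeforestationSchedule | None = None,
) -> dict[str, np.ndarray]:
    """Future tree/herb layers via the pixel-wise deforestation projector."""
    schedule = schedule or DeforestationSchedule()
    state = LandCoverState(
        tree_pct=landscape.stack.layers["tree_pct"],
        herb_pct=landscape.stack.layers["herb_pct"],
        bare_pct=landscape.bare_pct,
        year=schedule.year_start,
    )
    future = project_landcover(state, schedule)
    return {"tree_pct": future.tree_pct, "herb_pct": future.herb_pct}


def build_scenarios(
    landscape: SyntheticLandscape,
    schedule: DeforestationSchedule | None = None,
    **climate_kwargs,
) -> list[ScenarioSpec]:
    """The three standard scenarios over a synthetic landscape.

    Each scenario's future stack differs from the recent stack only in the
    scenario's own layers (climate layers, land-cover layers, or both).
    """
    recent = landscape.stack
    fut_climate = make_future_climate(landscape, **climate_kwargs)
    fut_cover = make_future_landcover(landscape, schedule)
    return [
        ScenarioSpec("climate_only", recent, recent.replace_layers(fut_climate, epoch="future")),
        ScenarioSpec("landcover_only", recent, recent.replace_layers(fut_cover, epoch="future")),
        ScenarioSpec(
            "combined",
            recent,
            recent.replace_layers({**fut_climate, **fut_cover}, epoch="future"),
        ),
    ]


def true_richness_change(
    taxa: list[VirtualTaxon],
    recent: EnvStack,
    future: EnvStack,
) -> np.ndarray:
    """Ground-truth richness change from the taxa's own coefficients.

    Per pixel: sum over taxa of (in future true range) - (in recent true
    range); nodata in either epoch propagates.
    """
    if recent.meta.shape != future.meta.shape:
        raise AlignmentError("recent and future stacks have mismatched shapes")
    change = np.zeros(recent.meta.shape)
    invalid = ~(recent.land_mask & future.land_mask)
    for t in taxa:
        change += t.true_range(future) - t.true_range(recent)
    change[invalid] = np.nan
    return change
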