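"""Fractional land-cover accounting and pixel-wise deforestation projection.

A land-cover state holds per-pixel percentages of tree (T), herbaceous (H)
and bare (B) cover with T + H + B = 100 at every valid pixel.  Deforestation
is projected at a constant annual rate, linear on the baseline tree cover:
over ``y`` years each pixel loses ``T * r * y`` percentage points of tree
cover (floored so tree cover never goes negative), and herbaceous cover
gains exactly the tree loss.  Bare ground (rock, soil) is assumed static.
Pixels are independent: there is no spatial targeting of loss.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .exceptions import AlignmentError, ConfigurationError

log = logging.getLogger(__name__)


@dataclass
class LandCoverState:
    """Per-pixel fractional cover (percent) for one calendar year."""

    tree_pct: np.ndarray
    herb_pct: np.ndarray
    bare_pct: np.ndarray
    year: int

    def __post_init__(self) -> None:
        if not (self.tree_pct.shape == self.herb_pct.shape == self.bare_pct.shape):
            raise AlignmentError("land-cover grids have mismatched shapes")

    def total(self) -> np.ndarray:
        return self.tree_pct + self.herb_pct + self.bare_pct


@dataclass
class DeforestationSchedule:
    """Constant annual tree-loss rate, accumulated linearly on the baseline.

    The default (0.28 %/yr over 2001-2080) removes
    0.0028 * 79 = 22.12 % of baseline tree cover wherever the floor at
    zero is not hit.
    """

    annual_rate: float = 0.0028
    year_start: int = 2001
    year_end: int = 2080

    def __post_init__(self) -> None:
        if self.annual_rate < 0:
            raise ConfigurationError("deforestation rate must be non-negative")
        if self.year_end < self.year_start:
            raise ConfigurationError("year_end must be >= year_start")

    @property
    def total_fraction(self) -> float:
        """Fraction of baseline tree cover lost over the whole horizon."""
        return self.annual_rate * (self.year_end - self.year_start)


def herb_baseline(tree_pct: np.ndarray, bare_pct: np.ndarray) -> np.ndarray:
    """Baseline herbaceous cover H = 100 - (T + B), clamped to [0, 100].

    Tree and bare layers come from different epochs of satellite fractional
    cover, so the difference can stray outside [0, 100] on inconsistent
    pixels; such clamp events are logged.
    """
    if tree_pct.shape != bare_pct.shape:
        raise AlignmentError("tree and bare grids have mismatched shapes")
    herb = 100.0 - (tree_pct + bare_pct)
    n_clamped = int(np.nansum((herb < 0) | (herb > 100)))
    if n_clamped:
        log.warning("herb_baseline: clamped %d pixel(s) to [0, 100]", n_clamped)
    return np.clip(herb, 0.0, 100.0)


def project_landcover(state: LandCoverState, schedule: DeforestationSchedule) -> LandCoverState:
    """Project tree-to-herb conversion to ``schedule.year_end``.

    Per pixel: ``loss = min(T, T * r * years)``; tree cover drops by the
    loss, herbaceous cover gains it, bare cover is unchanged, so total
    cover is conserved exactly.
    """
    loss = np.minimum(state.tree_pct, state.tree_pct * schedule.total_fraction)
    return LandCoverState(
        tree_pct=state.tree_pct - loss,
        herb_pct=state.herb_pct + loss,
        bare_pct=state.bare_pct.copy(),
        year=schedule.year_end,
    )
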