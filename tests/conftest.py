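"""Shared fixtures: small synthetic landscapes, taxa and SWD tables."""
import numpy as np
import pandas as pd
import pytest

import richstack as rs


@pytest.fixture(scope="session")
def landscape():
    """Small landscape for fast unit tests."""
    return rs.gen_landscape(40, 40, seed=11)


@pytest.fixture(scope="session")
def taxa(landscape):
    return rs.gen_virtual_taxa(landscape, n_taxa=4, seed=5)


@pytest.fixture(scope="session")
def occ_table(landscape, taxa):
    frames = [
        rs.sample_occurrences(t, landscape, n=60, seed=20 + i)
        for i, t in enumerate(taxa)
    ]
    return pd.concat(frames, ignore_index=True)


@pytest.fixture(scope="session")
def swd_table(landscape, occ_table):
    occ, _ = rs.filter_occurrences(occ_table, landscape.stack, landscape.dem)
    bg = rs.sample_background(landscape.stack, 600, seed=3)
    return rs.build_swd(occ, bg, landscape.stack, rs.ALL_LAYERS)


@pytest.fixture(scope="session")
def feature_set(swd_table):
    _, bg = rs.swd_split(swd_table)
    return rs.build_features(bg)


def tiny_meta(n_rows=4, n_cols=5, cell=1.0, x0=0.0, y0=4.0):
    return rs.GridMeta(n_rows=n_rows, n_cols=n_cols, cell_size=cell, origin_x=x0, origin_y=y0)


@pytest.fixture
def meta():
    return tiny_meta()


def make_stack(meta, layer_values: dict, mask=None):
    layers = {k: np.asarray(v, dtype=float) for k, v in layer_values.items()}
    if mask is None:
        mask = np.ones(meta.shape, dtype=bool)
        for arr in layers.values():
            mask &= np.isfinite(arr)
    for arr in layers.values():
        arr[~mask] = np.nan
    return rs.EnvStack(meta=meta, layers=layers, land_mask=mask)
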