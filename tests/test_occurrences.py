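"""Occurrence filter chain, genus aggregation, background sampling, SWD."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats

import richstack as rs
from richstack.exceptions import CapacityError, ConfigurationError

from conftest import make_stack, tiny_meta


def _rec(taxon, lon, lat, year=2000, elev=100.0):
    return {"taxon": taxon, "level": "species", "lon": lon, "lat": lat,
            "year": year, "elevation": elev}


@pytest.fixture
def small_stack(meta):
    # 4x5 grid, all land except cell (3, 4)
    vals = np.arange(20, dtype=float).reshape(4, 5)
    mask = np.ones((4, 5), dtype=bool)
    mask[3, 4] = False
    return make_stack(meta, {"temp": vals.copy(), "prec": (vals * 2).copy()}, mask)


@pytest.fixture
def dem(small_stack):
    d = np.full((4, 5), 500.0)
    d[0, 3] = 3000.0  # one high cell
    d[~small_stack.land_mask] = np.nan
    return d


class TestFilterOccurrences:
    def test_manual_trace_of_four_rules(self, small_stack, dem):
        # two records of A in one cell, one too old, one too high, two valid
        occ = pd.DataFrame(
            [
                _rec("A a", 0.5, 3.5),          # kept
                _rec("A a", 0.6, 3.6),          # duplicate cell (0,0) -> dropped
                _rec("A a", 1.5, 3.5, year=1975),  # pre-cutoff -> dropped
                _rec("A a", 3.5, 3.5),          # kept (cell 0,3 is high...)
                _rec("B b", 2.5, 2.5),          # kept
                _rec("B b", 3.5, 2.5),          # kept
            ]
        )
        occ.loc[3, "lon"], occ.loc[3, "lat"] = 3.5, 3.9  # cell (0,3): DEM 3000 -> dropped
        out, rep = rs.filter_occurrences(occ, small_stack, dem, min_records=1)
        assert rep.n_input == 6
        assert rep.n_after_dedup == 5
        assert rep.n_after_date == 4
        assert rep.n_after_elevation == 3
        assert len(out) == 3

    @pytest.mark.parametrize("n, kept", [(10, 0), (11, 11)])
    def test_minimum_record_rule_is_strict(self, small_stack, dem, n, kept):
        # n distinct low-elevation land cells
        rows, cols = np.nonzero(small_stack.land_mask)
        ok = ~((rows == 0) & (cols == 3))  # skip the 3000 m cell
        rows, cols = rows[ok][:n], cols[ok][:n]
        occ = pd.DataFrame(
            [_rec("A a", c + 0.5, 4.0 - r - 0.5) for r, c in zip(rows, cols)]
        )
        out, rep = rs.filter_occurrences(occ, small_stack, dem)
        if kept:
            assert len(out) >= 10 and rep.taxa_retained == 1
        else:
            assert len(out) == 0 and rep.taxa_dropped_low_n == 1

    def test_all_duplicates_collapse_to_one(self, small_stack, dem):
        occ = pd.DataFrame([_rec("A a", 1.5, 2.5)] * 7)
        out, rep = rs.filter_occurrences(occ, small_stack, dem, min_records=1)
        assert rep.n_after_dedup == 1 and len(out) == 1

    def test_filtering_is_idempotent(self, small_stack, dem):
        rng = np.random.default_rng(4)
        occ = pd.DataFrame(
            [_rec("A a", rng.uniform(0, 5), rng.uniform(0, 4),
                  year=int(rng.integers(1970, 2010))) for _ in range(60)]
        )
        once, _ = rs.filter_occurrences(occ, small_stack, dem, min_records=1)
        twice, _ = rs.filter_occurrences(once, small_stack, dem, min_records=1)
        pd.testing.assert_frame_equal(once, twice)

    def test_empty_input_gives_empty_output_and_report(self, small_stack, dem):
        out, rep = rs.filter_occurrences(pd.DataFrame(columns=list(rs.io.OCC_COLUMNS)),
                                         small_stack, dem)
        assert len(out) == 0 and rep.n_input == 0


class TestAggregateToGenus:
    def test_congeners_pool_under_genus(self, meta):
        occ = pd.DataFrame(
            [_rec("Aloe vera", 0.5, 3.5), _rec("Aloe vera", 1.5, 3.5),
             _rec("Aloe ferox", 2.5, 3.5), _rec("Aloe ferox", 3.5, 3.5)]
        )
        out = rs.aggregate_to_genus(occ, meta)
        assert (out["taxon"] == "Aloe").all()
        assert (out["level"] == "genus").all()
        assert len(out) == 4

    def test_congeners_sharing_a_cell_dedup(self, meta):
        occ = pd.DataFrame(
            [_rec("Aloe vera", 0.5, 3.5), _rec("Aloe ferox", 0.6, 3.4)]
        )
        out = rs.aggregate_to_genus(occ, meta)
        assert len(out) == 1

    def test_single_species_genus_is_relabelled_identity(self, meta):
        occ = pd.DataFrame([_rec("Uapaca bojeri", 0.5, 3.5), _rec("Uapaca bojeri", 1.5, 2.5)])
        out = rs.aggregate_to_genus(occ, meta)
        assert len(out) == 2 and (out["taxon"] == "Uapaca").all()

    def test_non_binomial_name_kept_whole(self, meta):
        occ = pd.DataFrame([_rec("Indet", 0.5, 3.5)])
        out = rs.aggregate_to_genus(occ, meta)
        assert out["taxon"].iloc[0] == "Indet"


class TestSampleBackground:
    def test_deterministic_distinct_on_mask(self, small_stack):
        a = rs.sample_background(small_stack, 10, seed=7)
        b = rs.sample_background(small_stack, 10, seed=7)
        pd.testing.assert_frame_equal(a, b)
        cells = set(zip(a["row"], a["col"]))
        assert len(cells) == 10
        assert all(small_stack.land_mask[r, c] for r, c in cells)

    def test_exhaustive_draw_covers_all_land(self, small_stack):
        n = small_stack.n_land
        pts = rs.sample_background(small_stack, n, seed=1)
        assert len(pts) == n and len(set(zip(pts.row, pts.col))) == n

    def test_overdraw_raises_capacity_error(self, small_stack):
        with pytest.raises(CapacityError):
            rs.sample_background(small_stack, small_stack.n_land + 1, seed=0)

    def test_sampling_is_uniform_over_cells(self, small_stack):
        # chi-square goodness of fit over >=1e4 draws
        counts = np.zeros(small_stack.meta.shape)
        for seed in range(1000):
            pts = rs.sample_background(small_stack, 12, seed=seed)
            counts[pts["row"], pts["col"]] += 1
        observed = counts[small_stack.land_mask]
        assert observed.sum() == 12_000
        p = stats.chisquare(observed).pvalue
        assert p > 0.01


class TestBuildSWD:
    def test_covariate_extraction_identity(self, small_stack):
        occ = pd.DataFrame([_rec("A a", 2.5, 3.5)])  # cell (0, 2): temp 2, prec 4
        bg = rs.sample_background(small_stack, 3, seed=0)
        swd = rs.build_swd(occ, bg, small_stack, ["temp", "prec"])
        row = swd[swd["species"] == "A a"].iloc[0]
        assert row["temp"] == 2.0 and row["prec"] == 4.0
        assert len(swd) == 4

    def test_point_on_invalid_cell_dropped(self, small_stack):
        occ = pd.DataFrame([_rec("A a", 4.5, 0.5)])  # cell (3,4) is off-mask
        swd = rs.build_swd(occ, rs.sample_background(small_stack, 2, seed=0),
                           small_stack, ["temp"])
        assert (swd["species"] == "background").all()

    def test_unknown_layer_raises(self, small_stack):
        with pytest.raises(ConfigurationError):
            rs.build_swd(pd.DataFrame([_rec("A a", 0.5, 3.5)]),
                         rs.sample_background(small_stack, 2, seed=0),
                         small_stack, ["nope"])

    def test_subset_controls_covariate_count(self, landscape, occ_table):
        occ, _ = rs.filter_occurrences(occ_table, landscape.stack, landscape.dem)
        bg = rs.sample_background(landscape.stack, 50, seed=2)
        swd = rs.build_swd(occ, bg, landscape.stack, rs.CLIMATE_LAYERS)
        assert len(rs.swd_covariates(swd)) == 9
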