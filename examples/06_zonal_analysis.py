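"""Zonal analysis of a richness-change map.

Summarizes a change map over ecoregions and over elevation bands built two
ways — equal elevation intervals (equal steps, very unequal areas on a
right-skewed DEM) and equal areas (equal pixel counts, very unequal
elevation spans) — with area-normalized means for cross-zone comparison.
"""
import pandas as pd

import richstack as rs

landscape = rs.gen_landscape(60, 60, seed=42)
taxa = rs.gen_virtual_taxa(landscape, n_taxa=12, seed=1)
occ = pd.concat(
    [rs.sample_occurrences(t, landscape, n=100, seed=10 + i)
     for i, t in enumerate(taxa)],
    ignore_index=True,
)
occ, _ = rs.filter_occurrences(occ, landscape.stack, landscape.dem)
scen = rs.build_scenarios(landscape)[2]  # combined
result = rs.run_factorial([scen], {"species": occ}, rules=("T2",),
                          n_background=2000, seed=7)
change = result.change[("combined", "T2_youden", "species")]

pd.set_option("display.width", 120)
for zones, label in [
    (rs.ecoregion_zones(landscape.ecoregions), "ecoregions"),
    (rs.equal_interval_bands(landscape.dem, 7), "equal-interval elevation bands"),
    (rs.equal_area_bands(landscape.dem, 7), "equal-area elevation bands"),
]:
    areas = rs.cell_area_grid(landscape.meta, cos_lat=True)
    stats = rs.zonal_change_stats(change, zones, cell_area_km2=areas)
    print(f"\nchange in richness by {label}:")
    cols = ["name", "n_pixels", "mean", "sd", "min", "max", "mean_per_km2"]
    print(stats[cols].round(2).to_string(index=False))
print("\n(mean = average per-pixel change in the zone; mean_per_km2 = zone "
      "total change / zone area, comparable across zones of different size)")
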