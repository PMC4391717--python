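"""Occurrence filtering and genus aggregation.

Samples presence records for each virtual taxon (probability proportional
to true suitability), then applies the standard record-hygiene chain:
per-cell deduplication, land-mask membership, a post-1980 collection-year
cutoff, a DEM elevation ceiling, and removal of taxa with 10 or fewer
surviving records.
"""
import pandas as pd

import richstack as rs

landscape = rs.gen_landscape(60, 60, seed=42)
taxa = rs.gen_virtual_taxa(landscape, n_taxa=10, seed=1)
occ = pd.concat(
    [rs.sample_occurrences(t, landscape, n=80, seed=10 + i)
     for i, t in enumerate(taxa)],
    ignore_index=True,
)

filtered, report = rs.filter_occurrences(occ, landscape.stack, landscape.dem)
print("filter chain (records surviving each stage):")
print(f"  input            {report.n_input}")
print(f"  after dedup      {report.n_after_dedup}")
print(f"  after land mask  {report.n_after_mask}")
print(f"  after year>=1981 {report.n_after_date}")
print(f"  after elev<2876  {report.n_after_elevation}")
print(f"  taxa retained    {report.taxa_retained} "
      f"(dropped for low n: {report.taxa_dropped_low_n})")

genus = rs.aggregate_to_genus(filtered, landscape.meta)
genus, _ = rs.filter_occurrences(genus, landscape.stack, landscape.dem)
print(f"\ngenus level: {genus['taxon'].nunique()} genera, {len(genus)} records "
      "(congeners pooled, re-deduplicated per cell)")
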