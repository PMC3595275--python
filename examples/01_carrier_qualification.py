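"""Qualify carriers at a candidate CNV region from segment-level calls.

Builds a 28-probe deletion region (merge-mode regime), hands the
qualifier three samples with different call morphologies, and prints the
resulting carrier statuses.
"""

import rarecnv as rc
from rarecnv.simulate import synthesize_probe_map

region = rc.RegionDefinition("sh2b1_like", "chr16", 28_731_428, 28_951_376,
                             "loss", flank_bp=500_000)
probe_map = synthesize_probe_map([region], {"sh2b1_like": 28})
index = rc.build_region_probe_index([region], probe_map)
pos = probe_map.positions_in("chr16", region.start, region.end)

samples = {
    # one clean deletion spanning the whole region
    "clean_del": [rc.SegmentCall("clean_del", "chr16", region.start - 2000,
                                 region.end + 2000, 1, 28)],
    # caller split the event into two fragments covering 15/28 probes
    "fragmented": [
        rc.SegmentCall("fragmented", "chr16", int(pos[0]), int(pos[7]), 1, 8),
        rc.SegmentCall("fragmented", "chr16", int(pos[21]), int(pos[27]), 1, 7),
    ],
    # a duplication instead of the expected deletion
    "reciprocal": [rc.SegmentCall("reciprocal", "chr16", region.start - 2000,
                                  region.end + 2000, 3, 28)],
}

print(f"region {region.region_id}: {index.n_probes_region(region.region_id)}"
      f" probes, expected class {region.variant_class}")
for name, calls in samples.items():
    res = rc.qualify_sample_region(calls, region, index, probe_map)
    if res.status == "non_carrier":
        res = rc.qualify_reciprocal(calls, region, index, probe_map)
    flag = " (provisional, pending review)" if res.provisional else ""
    print(f"  {name:11s} -> {res.status}{flag}, "
          f"{res.supporting_probes} supporting probes")

# The clean and fragmented samples both qualify as (provisional) deletion
# carriers because >50% of in-region probes are altered; the duplication is
# scored as a reciprocal carrier, not a carrier of the expected class.
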