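"""Recombination-rate map conversion to PLINK and SHAPEIT dialects.

Genetic length of an interval = (end - start) * rate/bp * 100 cM, so
1 Mb at 1e-8/bp is 1 cM.  Gaps between rate intervals contribute 0 cM;
positions outside the map clamp to the terminal values.
"""

import pandas as pd

import admixqc as aq
from admixqc.containers import make_markers

intervals = pd.DataFrame(
    [("chr1", 0, 1_000_000, 1e-8),      # 1 cM
     ("chr1", 1_000_000, 3_000_000, 2e-8),  # + 4 cM
     ("chr1", 5_000_000, 6_000_000, 1e-8)], # gap 3-5 Mb: flat
    columns=["chrom", "start", "end", "rate"],
)
gmap = aq.cm_from_rate(intervals)
for pos in (1_000_000, 3_000_000, 4_000_000, 6_000_000):
    print(f"cumulative cM at {pos:>9,} bp: {gmap.interpolate('chr1', pos):.3f}")

markers = make_markers(["chr1"] * 4, [500_000, 2_000_000, 4_500_000, 5_500_000])
aq.write_map(gmap, markers, "scratch_markers.plink.map", "plink")
aq.write_map(gmap, markers, "scratch_markers.shapeit.map", "shapeit")
print("\nPLINK dialect (chrom, id, cM, bp):")
print(open("scratch_markers.plink.map").read().rstrip())
print("\nSHAPEIT dialect (pos, chr, cM):")
print(open("scratch_markers.shapeit.map").read().rstrip())
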