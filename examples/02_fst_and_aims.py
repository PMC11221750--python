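"""Weir-Cockerham F_ST and ancestry-informative-marker selection.

Simulates 9+9 purebred founders at divergence 0.4, estimates per-marker
and weighted F_ST, counts markers fixed between the populations, and
selects an AIM panel (F_ST > 0.8, best marker per 100-kb window, strict
per-population and pooled LD pruning).
"""

import admixqc as aq

freqs = aq.simulate_founder_frequencies(20_000, 0.4, fixed_fraction=0.005, seed=10)
panel, pedigree, _ = aq.simulate_founders(freqs, (9, 9), seed=11)

refs0 = [s for s in panel.samples if s.startswith("OLV")]
refs1 = [s for s in panel.samples if s.startswith("YEL")]
assignment = {s: 0 for s in refs0} | {s: 1 for s in refs1}

table = aq.wc_fst_per_marker(panel, assignment)
wfst = aq.weighted_fst(table)
n_fixed, _ = aq.count_fixed_markers(table)
print(f"weighted F_ST (ratio of sums): {wfst:.6f}   (simulated target 0.4)")
print(f"markers fixed between the populations: {n_fixed}")

aims = aq.select_aims(table, panel, (refs0, refs1))
print(f"AIMs selected: {len(aims)} of {panel.n_markers} markers")
print("stage survival:",
      {s: int(aims.provenance[s].sum()) for s in ("stage2", "stage3", "stage4")})
print("first five AIMs (chrom:pos, F_ST):")
for (_, row), fst in list(zip(panel.markers.iloc[aims.marker_index].iterrows(), aims.fst))[:5]:
    print(f"  {row['chrom']}:{row['pos']}  {fst:.4f}")
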