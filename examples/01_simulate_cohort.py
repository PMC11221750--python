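"""Simulate a pedigreed two-population cohort with exact ancestry truth.

Builds two diverged founder populations (F_ST 0.4, 0.5% fixed
differences), crosses them into F1s, a backcross and an F2, and prints
the pedigree plus a text karyogram of the F1 (one olive and one yellow
haplotype per chromosome, by construction).
"""

import admixqc as aq

chrom_lengths = {f"chr{i}": 50_000_000 for i in range(1, 5)}
gmap = aq.uniform_map(chrom_lengths, rate=1e-8)  # 1 cM/Mb
freqs = aq.simulate_founder_frequencies(
    8000, fst_target=0.4, fixed_fraction=0.005, chrom_lengths=chrom_lengths, seed=1
)

design = {
    "founders": {"olive": 4, "yellow": 4},
    "crosses": [
        ("F1_001", "OLV001", "YEL001"),
        ("BC_001", "F1_001", "OLV002"),
        ("F2_001", "F1_001", "F1_001"),
    ],
}
panel, pedigree, truth = aq.simulate_pedigree(design, freqs, gmap, seed=2)

print(f"{panel.n_samples} samples x {panel.n_markers} markers")
print(pedigree.table.to_string(index=False))
print()

# global truth ancestry from the bp-weighted tracts: founders at 0/1,
# the F1 at exactly 0.5, the backcross near 0.75
print(aq.global_from_tracts(truth).to_string(index=False))
print()

print("F1 truth karyogram (O = olive, Y = yellow; rows are haplotypes):")
print(aq.text_karyogram(truth, "F1_001", width=60))
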