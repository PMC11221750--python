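"""Trio Mendelian local-ancestry audit and pedigree-label audit.

A child cannot be homozygous for ancestry X at a locus where a parent
is homozygous for Y != X.  On clean truth tracts the inconsistency
fraction is zero; corrupting a known fraction of the offspring's calls
recovers that fraction.  The label audit flags animals whose pedigree
taxon disagrees with their estimated ancestry (olive/yellow-labelled
below 90%, cross-labelled above 90% or pure-like above 99%).
"""

import numpy as np
import pandas as pd

import admixqc as aq
from admixqc.containers import Pedigree

chrom_lengths = {f"chr{i}": 50_000_000 for i in range(1, 5)}
gmap = aq.uniform_map(chrom_lengths)
freqs = aq.simulate_founder_frequencies(6000, 0.4, 0.005, chrom_lengths, seed=50)
design = {"founders": {"olive": 2, "yellow": 2},
          "crosses": [("F1_001", "OLV001", "YEL001")]}
panel, pedigree, truth = aq.simulate_pedigree(design, freqs, gmap, seed=51)

off = truth.subset_samples(["F1_001"])
sire = truth.subset_samples(["OLV001"])
dam = truth.subset_samples(["YEL001"])
clean = aq.trio_consistency(off, sire, dam)
print(f"trio inconsistency on truth tracts: {clean.attrs['fraction_flagged']:.4%}")

rng = np.random.default_rng(52)
bad = off.copy()
corrupt = rng.random(off.n_markers) < 0.05
bad.ancestry[0, :, corrupt] = 1  # homozygous-opposite of the olive sire
audit = aq.trio_consistency(bad, sire, dam)
print(f"after corrupting {corrupt.mean():.2%} of offspring calls: "
      f"{audit.attrs['fraction_flagged']:.2%} flagged")

# label audit on a hand-built table: one mislabelled 'olive', one
# cross-labelled animal with near-purebred ancestry
rows = [("A1", "0", "0", "M", "olive", 0), ("A2", "0", "0", "F", "olive", 0),
        ("A3", "0", "0", "F", "cross", 1)]
ped = Pedigree(pd.DataFrame(rows, columns=Pedigree.COLUMNS))
est = pd.DataFrame(
    [("A1", 0.997, 0.003, "likelihood", 5000),
     ("A2", 0.62, 0.38, "likelihood", 5000),
     ("A3", 0.995, 0.005, "likelihood", 5000)],
    columns=["sample", "q_olive", "q_yellow", "method", "n_used"],
)
flags = aq.audit_pedigree_labels(est, ped)
print("\npedigree-label audit:")
print(flags.to_string(index=False))
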