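"""Supervised and unsupervised two-way global ancestry estimation.

Estimates each sample's olive proportion q by maximizing the binomial
admixture likelihood against reference allele frequencies, and runs
the unsupervised K=2 fit to rediscover the purebred founders
(> 99% single-population ancestry).
"""

import numpy as np

import admixqc as aq

freqs = aq.simulate_founder_frequencies(5000, 0.4, 0.005, seed=20)
gmap = aq.uniform_map({f"chr{i}": 50_000_000 for i in range(1, 5)})
design = {
    "founders": {"olive": 5, "yellow": 5},
    "crosses": [("F1_001", "OLV001", "YEL001"), ("BC_001", "F1_001", "OLV002")],
}
panel, pedigree, truth = aq.simulate_pedigree(design, freqs, gmap, seed=21)

est = aq.estimate_admixture_supervised(panel.dosages(), freqs, samples=panel.samples)
truth_q = aq.global_from_tracts(truth).set_index("sample")["q_olive"]
print("sample     q_olive (MLE)   q_olive (truth tracts)")
for _, row in est.iterrows():
    print(f"{row['sample']:<10} {row['q_olive']:.4f}          {truth_q[row['sample']]:.4f}")
err = np.abs(est.set_index("sample")["q_olive"] - truth_q).max()
print(f"max |error| vs truth: {err:.4f}")

labels = dict(zip(pedigree.table["id"], pedigree.table["taxon"]))
fit = aq.estimate_admixture_unsupervised_k2(panel, seed=22, labels=labels)
pure = aq.discover_purebreds(fit.ancestry, threshold=0.99)
print(f"\nunsupervised fit converged={fit.converged} after {fit.n_iter} iterations")
print(f"samples with >99% single-population ancestry: {sorted(pure)}")
print("(these are exactly the simulated purebred founders)")
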