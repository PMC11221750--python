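"""End-to-end demo pipeline on synthetic data.

simulate -> degrade -> filter -> F_ST / AIMs -> supervised global
ancestry -> HMM local ancestry -> phase-switch QC -> trio audit ->
pedigree-label audit.  Every stage draws its seed from one master
generator, so a re-run with the same config and seed reproduces every
output byte-identically.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from . import ancestry, genmap, io, phaseqc, popgen, simdata
from .containers import HmmConfig, PopulationFrequencies

DEFAULT_CONFIG = {
    "n_markers": 20_000,
    "fst_target": 0.4,
    "fixed_fraction": 0.005,
    "n_chroms": 4,
    "chrom_length": 50_000_000,
    "recomb_rate": 1e-8,
    "n_olive": 9,
    "n_yellow": 9,
    "n_f1": 4,
    "n_backcross": 2,
    "n_f2": 2,
    "switch_rate": 2.0,
    "missing_rate": 0.0,
    "max_missing": 0.0,
    "min_maf": 0.05,
    "fst_min": 0.8,
    "window_bp": 100_000,
    "hmm_generations": 8.0,
    "major_threshold": 0.90,
    "pure_threshold": 0.99,
}


def build_design(cfg: dict) -> dict:
    """Founders plus F1s, backcrosses and F2s from distinct founder pairs."""
    n_olive, n_yellow = cfg["n_olive"], cfg["n_yellow"]
    crosses = []
    f1s = []
    for i in range(cfg["n_f1"]):
        sire = f"OLV{(i % n_olive) + 1:03d}"
        dam = f"YEL{(i % n_yellow) + 1:03d}"
        child = f"F1_{i + 1:03d}"
        crosses.append((child, sire, dam))
        f1s.append(child)
    for i in range(cfg["n_backcross"]):
        crosses.append((f"BC_{i + 1:03d}", f1s[i % len(f1s)], f"OLV{(i % n_olive) + 1:03d}"))
    for i in range(cfg["n_f2"]):
        a = f1s[i % len(f1s)]
        b = f1s[(i + 1) % len(f1s)]
        crosses.append((f"F2_{i + 1:03d}", a, b))
    return {
        "founders": {"olive": n_olive, "yellow": n_yellow},
        "crosses": crosses,
    }


def run_pipeline(config: dict | None = None, out_dir=None, seed: int = 0) -> dict:
    """Run the full synthetic-data pipeline; returns in-memory artifacts.

    When ``out_dir`` is given, all tables and a run log are written
    there as plain-text files.
    """
    cfg = dict(DEFAULT_CONFIG)
    if config:
        unknown = set(config) - set(DEFAULT_CONFIG)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg.update(config)
    master = np.random.default_rng(seed)
    stage_seed = lambda: int(master.integers(2**31))
    log = {"seed": seed, "config": cfg, "stages": {}}

    chrom_lengths = {
        f"chr{i + 1}": int(cfg["chrom_length"]) for i in range(int(cfg["n_chroms"]))
    }
    gmap = genmap.uniform_map(chrom_lengths, rate=cfg["recomb_rate"])

    freqs = simdata.simulate_founder_frequencies(
        int(cfg["n_markers"]), cfg["fst_target"], cfg["fixed_fraction"],
        chrom_lengths, seed=stage_seed(),
    )
    design = build_design(cfg)
    panel, pedigree, truth = simdata.simulate_pedigree(design, freqs, gmap, seed=stage_seed())
    f1_samples = [c[0] for c in design["crosses"] if c[0].startswith("F1_")]

    panel_sw, truth_sw, switches = simdata.inject_phase_switches(
        panel, truth, rate=cfg["switch_rate"], gmap=gmap, samples=f1_samples,
        seed=stage_seed(),
    )
    if cfg["missing_rate"] > 0:
        panel_sw = simdata.degrade_genotypes(panel_sw, cfg["missing_rate"], seed=stage_seed())
    log["stages"]["simulate"] = {
        "n_markers": int(panel.n_markers),
        "n_samples": int(panel.n_samples),
        "n_injected_switches": int(len(switches)),
    }

    keep = popgen.filter_markers(panel_sw, cfg["max_missing"], cfg["min_maf"])
    panel_f = panel_sw.subset_markers(keep)
    truth_f = _subset_tracts(truth_sw, keep)
    freqs_f = PopulationFrequencies(
        panel_f.markers, freqs.freq[keep], freqs.ancestral[keep]
    )
    log["stages"]["filter"] = {"n_markers_in": int(panel_sw.n_markers),
                               "n_markers_kept": int(len(keep))}

    founders = pedigree.founders()
    taxon = pedigree.table.set_index("id")["taxon"]
    refs0 = [s for s in founders if taxon[s] == "olive"]
    refs1 = [s for s in founders if taxon[s] == "yellow"]
    assignment = {s: 0 for s in refs0} | {s: 1 for s in refs1}
    fst_table = popgen.wc_fst_per_marker(panel_f.subset_samples(refs0 + refs1), assignment)
    wfst = popgen.weighted_fst(fst_table)
    n_fixed, _ = popgen.count_fixed_markers(fst_table)
    aims = popgen.select_aims(
        fst_table, panel_f, (refs0, refs1),
        fst_min=cfg["fst_min"], window_bp=int(cfg["window_bp"]),
    )
    log["stages"]["popgen"] = {
        "weighted_fst": wfst, "n_fixed_markers": int(n_fixed), "n_aims": int(len(aims)),
    }

    # reference frequencies observed in the purebred founders
    ref_freqs = PopulationFrequencies(
        panel_f.markers,
        np.stack([fst_table["p0"].to_numpy(), fst_table["p1"].to_numpy()], axis=1),
        fst_table[["p0", "p1"]].mean(axis=1).to_numpy(),
    )
    global_est = ancestry.estimate_admixture_supervised(
        panel_f.dosages(), ref_freqs, samples=panel_f.samples
    )

    hmm_cfg = HmmConfig(generations=cfg["hmm_generations"])
    la = ancestry.hmm_local_ancestry_panel(panel_f, ref_freqs, gmap, hmm_cfg)
    global_tracts = ancestry.global_from_tracts(la)

    panel_unk, la_unk, corrections = phaseqc.unkink_all(panel_f, la, samples=f1_samples)
    switch_report = phaseqc.f1_switch_report(la, la_unk, samples=f1_samples) if f1_samples else None

    trio_table = None
    if f1_samples:
        child = f1_samples[0]
        row = pedigree.table.set_index("id").loc[child]
        trio_table = phaseqc.trio_consistency(
            la_unk.subset_samples([child]),
            la_unk.subset_samples([row["sire"]]),
            la_unk.subset_samples([row["dam"]]),
        )
    audit = phaseqc.audit_pedigree_labels(
        global_est, pedigree, major=cfg["major_threshold"], pure=cfg["pure_threshold"]
    )
    log["stages"]["phaseqc"] = {
        "corrections": corrections,
        "pct_reduction": None if switch_report is None
        else float(switch_report.iloc[-1]["pct_reduction"]),
        "trio_fraction_flagged": None if trio_table is None
        else trio_table.attrs["fraction_flagged"],
        "n_audit_flags": int((audit["flag"] != "unaudited").sum()),
    }

    artifacts = {
        "gmap": gmap, "freqs": freqs_f, "panel": panel_f, "pedigree": pedigree,
        "truth": truth_f, "switches": switches, "fst_table": fst_table,
        "weighted_fst": wfst, "n_fixed": n_fixed, "aims": aims,
        "global_supervised": global_est, "local_ancestry": la,
        "global_tracts": global_tracts, "unkinked_panel": panel_unk,
        "unkinked_tracts": la_unk, "switch_report": switch_report,
        "trio": trio_table, "audit": audit, "log": log,
    }
    if out_dir is not None:
        _write_artifacts(artifacts, Path(out_dir))
    return artifacts


def _subset_tracts(tracts, index):
    from .containers import TractSet

    index = np.asarray(index)
    return TractSet(
        tracts.markers.iloc[index].reset_index(drop=True),
        list(tracts.samples),
        tracts.ancestry[:, :, index],
        dict(tracts.codes),
    )


def _write_artifacts(art: dict, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    io.write_vcf(art["panel"], out_dir / "cohort.vcf")
    io.write_pedigree(art["pedigree"], out_dir / "pedigree.tsv")
    io.write_tracts_bed(art["truth"], out_dir / "truth_tracts.bed")
    genmap.write_map(art["gmap"], art["panel"].markers, out_dir / "markers.plink.map", "plink")
    genmap.write_map(art["gmap"], art["panel"].markers, out_dir / "markers.shapeit.map", "shapeit")
    art["fst_table"].to_csv(out_dir / "fst.tsv", sep="\t", index=False, float_format="%.8g")
    aims = art["aims"]
    mk = art["panel"].markers.iloc[aims.marker_index]
    with open(out_dir / "aims.txt", "w") as fh:
        for (_, row), fst in zip(mk.iterrows(), aims.fst):
            fh.write(f"{row['chrom']}:{row['pos']}\t{fst:.6f}\n")
    io.write_global_ancestry(art["global_supervised"], out_dir / "global_supervised.tsv")
    io.write_global_ancestry(art["global_tracts"], out_dir / "global_from_tracts.tsv")
    ancestry.write_msp(art["local_ancestry"], art["gmap"], out_dir / "local_ancestry.msp.tsv")
    if art["switch_report"] is not None:
        art["switch_report"].to_csv(out_dir / "switch_report.tsv", sep="\t", index=False)
    if art["trio"] is not None:
        art["trio"].to_csv(out_dir / "trio_audit.tsv", sep="\t", index=False)
        (out_dir / "trio_summary.txt").write_text(
            f"fraction_flagged\t{art['trio'].attrs['fraction_flagged']:.6f}\n"
        )
    art["audit"].to_csv(out_dir / "pedigree_audit.tsv", sep="\t", index=False)
    with open(out_dir / "run_log.json", "w") as fh:
        json.dump(art["log"], fh, indent=2, sort_keys=True)
        fh.write("\n")
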