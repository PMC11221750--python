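"""Phase-switch detection, unkinking, and ancestry-based auditing.

A statistically phased F1 hybrid should carry, on every chromosome,
one fully olive and one fully yellow haplotype.  A phase-switch error
manifests as a *joint* ancestry switch: at the same inter-marker
boundary, haplotype 0 changes X -> Y while haplotype 1 changes Y -> X.
Unkinking exchanges the haplotypes' suffixes at each such boundary,
which removes the kink while preserving the genotype (the per-marker
allele multiset) and the sample's global ancestry.  One-sided ancestry
changes are genuine admixture signals and are never corrected.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import HaplotypePanel, Pedigree, TractSet, chrom_slices


def tract_statistics(tracts: TractSet) -> pd.DataFrame:
    """Per-sample tract and switch counts.

    Switches are tract boundaries: per haplotype per chromosome,
    tracts - 1, summed.  Returns a table (sample, n_tracts, n_switches,
    n_joint_switches).
    """
    tab = tracts.tracts()
    rows = []
    for sample in tracts.samples:
        grp = tab[tab["sample"] == sample]
        n_tracts = len(grp)
        per_chrom = grp.groupby(["hap", "chrom"]).size()
        n_switches = int((per_chrom - 1).sum())
        joint = detect_joint_switches(tracts, sample)
        rows.append((sample, int(n_tracts), n_switches, len(joint)))
    return pd.DataFrame(rows, columns=["sample", "n_tracts", "n_switches", "n_joint_switches"])


def detect_joint_switches(tracts: TractSet, sample: str) -> pd.DataFrame:
    """Boundaries where both haplotypes swap ancestry complementarily.

    Returns (chrom, boundary, pos): boundary b means the change happens
    between local markers b-1 and b; pos is the 1-based position of
    marker b.  Only exact joint, complementary changes qualify.
    """
    si = tracts.sample_index(sample)
    pos = tracts.markers["pos"].to_numpy()
    rows = []
    for chrom, sl in chrom_slices(tracts.markers):
        a0 = tracts.ancestry[si, 0, sl]
        a1 = tracts.ancestry[si, 1, sl]
        joint = (
            (a0[1:] != a0[:-1])
            & (a1[1:] != a1[:-1])
            & (a0[:-1] == a1[1:])
            & (a1[:-1] == a0[1:])
        )
        for b in np.flatnonzero(joint) + 1:
            rows.append((chrom, int(b), int(pos[sl.start + b])))
    return pd.DataFrame(rows, columns=["chrom", "boundary", "pos"])


def unkink(
    panel: HaplotypePanel,
    tracts: TractSet,
    sample: str,
) -> tuple[HaplotypePanel, TractSet, int]:
    """Correct phase-switch errors for one sample by suffix exchange.

    Scans each chromosome left to right; at every joint-switch boundary
    the two haplotypes' alleles and ancestry calls are exchanged from
    that boundary to the chromosome end.  Returns corrected copies of
    the panel and tract set plus the number of corrections.  Idempotent;
    never changes the allele multiset at any marker.
    """
    out_panel = panel.copy()
    out_tracts = tracts.copy()
    pi = out_panel.sample_index(sample)
    ti = out_tracts.sample_index(sample)
    n_corr = 0
    for chrom, sl in chrom_slices(out_tracts.markers):
        a = out_tracts.ancestry[ti, :, sl]
        h = out_panel.haplotypes[pi, :, sl]
        for b in range(1, a.shape[1]):
            joint = (
                a[0, b] != a[0, b - 1]
                and a[1, b] != a[1, b - 1]
                and a[0, b - 1] == a[1, b]
                and a[1, b - 1] == a[0, b]
            )
            if joint:
                a[:, b:] = a[::-1, b:]
                h[:, b:] = h[::-1, b:]
                n_corr += 1
    return out_panel, out_tracts, n_corr


def unkink_all(panel: HaplotypePanel, tracts: TractSet, samples=None):
    """Unkink every (or the given) sample; returns (panel, tracts, per-sample counts)."""
    samples = samples if samples is not None else list(panel.samples)
    counts = {}
    for sample in samples:
        panel, tracts, n = unkink(panel, tracts, sample)
        counts[sample] = n
    return panel, tracts, counts


def f1_switch_report(before: TractSet, after: TractSet, samples=None) -> pd.DataFrame:
    """Per-sample and aggregate switch reduction after correction.

    Percent reduction = 100 * (before - after) / before, computed on
    joint-switch counts; a sample with zero switches before correction
    reports 0 with the ``undefined`` flag set.  The last row
    ("__all__") aggregates the cohort.
    """
    samples = samples if samples is not None else list(before.samples)
    stats_b = tract_statistics(before.subset_samples(samples)).set_index("sample")
    stats_a = tract_statistics(after.subset_samples(samples)).set_index("sample")
    rows = []
    for sample in samples:
        b = int(stats_b.loc[sample, "n_joint_switches"])
        a = int(stats_a.loc[sample, "n_joint_switches"])
        undefined = b == 0
        red = 0.0 if undefined else 100.0 * (b - a) / b
        rows.append((sample, b, a, red, undefined))
    tb = sum(r[1] for r in rows)
    ta = sum(r[2] for r in rows)
    rows.append(("__all__", tb, ta, 0.0 if tb == 0 else 100.0 * (tb - ta) / tb, tb == 0))
    return pd.DataFrame(
        rows, columns=["sample", "switches_before", "switches_after", "pct_reduction", "undefined"]
    )


def trio_consistency(
    offspring: TractSet,
    sire: TractSet,
    dam: TractSet,
    offspring_sample: str | None = None,
    sire_sample: str | None = None,
    dam_sample: str | None = None,
) -> pd.DataFrame:
    """Mendelian local-ancestry audit of a parent-offspring trio.

    A marker is inconsistent when the offspring carries two copies of
    ancestry X while at least one parent carries two copies of Y != X:
    that parent must transmit a Y haplotype, so the offspring needs at
    least one copy of Y.  Heterozygous-ancestry configurations are
    never flagged.  All three tract sets must share one marker grid.

    Returns a per-marker table with diplotype ancestries and the flag;
    the summary fraction is ``result.attrs["fraction_flagged"]``.
    """
    grids = [t.markers[["chrom", "pos"]].reset_index(drop=True) for t in (offspring, sire, dam)]
    if not (grids[0].equals(grids[1]) and grids[0].equals(grids[2])):
        raise ValueError("trio tract sets are on different marker grids")

    def _diplo(t: TractSet, sample):
        si = t.sample_index(sample) if sample is not None else 0
        return t.ancestry[si, 0], t.ancestry[si, 1]

    o0, o1 = _diplo(offspring, offspring_sample)
    s0, s1 = _diplo(sire, sire_sample)
    d0, d1 = _diplo(dam, dam_sample)

    o_hom = o0 == o1
    flags = np.zeros(len(o0), dtype=bool)
    for p0, p1 in ((s0, s1), (d0, d1)):
        p_hom_other = (p0 == p1) & (p0 != o0)
        flags |= o_hom & p_hom_other

    out = offspring.markers[["chrom", "pos"]].copy()
    out["offspring"] = [f"{a}/{b}" for a, b in zip(o0, o1)]
    out["sire"] = [f"{a}/{b}" for a, b in zip(s0, s1)]
    out["dam"] = [f"{a}/{b}" for a, b in zip(d0, d1)]
    out["inconsistent"] = flags
    out.attrs["fraction_flagged"] = float(flags.mean()) if len(flags) else 0.0
    return out


def audit_pedigree_labels(
    ancestry: pd.DataFrame,
    pedigree: Pedigree,
    major: float = 0.90,
    pure: float = 0.99,
) -> pd.DataFrame:
    """Flag samples whose pedigree taxon disagrees with ancestry estimates.

    Flags (strict inequalities): olive-labelled with q_olive < major;
    yellow-labelled with q_yellow < major; cross-labelled with either
    ancestry > major, sub-flagged "pure-like" when > pure.  Samples
    missing a label or an estimate are listed with flag "unaudited".
    """
    est = ancestry.set_index("sample")
    labels = pedigree.table.set_index("id")["taxon"]
    rows = []
    audited = set(est.index) & set(labels.index)
    for sample in list(est.index) + [s for s in labels.index if s not in est.index]:
        if sample not in audited:
            q = float(est.loc[sample, "q_olive"]) if sample in est.index else np.nan
            rows.append((sample, labels.get(sample, None), q, "unaudited"))
            continue
        q = float(est.loc[sample, "q_olive"])
        label = labels[sample]
        flag = ""
        if label == "olive" and q < major:
            flag = "label-olive-low-ancestry"
        elif label == "yellow" and (1.0 - q) < major:
            flag = "label-yellow-low-ancestry"
        elif label == "cross" and (q > major or (1.0 - q) > major):
            flag = "cross-pure-like" if (q > pure or (1.0 - q) > pure) else "cross-major-ancestry"
        if flag:
            rows.append((sample, label, q, flag))
    return pd.DataFrame(rows, columns=["sample", "label", "q_olive", "flag"])


def text_karyogram(tracts: TractSet, sample: str, width: int = 80, chars="OY") -> str:
    """Plain-text karyogram: two rows per chromosome, one per haplotype.

    Each column spans chromosome_span / width bp; its character is the
    majority-bp ancestry within the column.
    """
    if width < 1:
        raise ValueError("width must be >= 1")
    tab = tracts.tracts()
    tab = tab[tab["sample"] == sample]
    lines = []
    for chrom, _ in chrom_slices(tracts.markers):
        grp = tab[tab["chrom"] == chrom]
        lo = grp["start"].min()
        hi = grp["end"].max()
        span = max(hi - lo, 1)
        lines.append(f"{chrom}")
        for hap in (0, 1):
            g = grp[grp["hap"] == hap]
            row = []
            for col in range(width):
                c0 = lo + span * col / width
                c1 = lo + span * (col + 1) / width
                bp = np.zeros(len(tracts.codes))
                for _, t in g.iterrows():
                    ov = min(t["end"], c1) - max(t["start"], c0)
                    if ov > 0:
                        bp[t["ancestry"]] += ov
                row.append(chars[int(np.argmax(bp))])
            lines.append("".join(row))
    return "\n".join(lines)
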