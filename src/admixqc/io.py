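"""File I/O: VCF, pedigree tables, truth-tract BED, run configs.

Coordinate conventions are centralised here: VCF and map files are
1-based; tract BED output is 0-based half-open.  Written VCFs are
deterministic byte-for-byte given the same panel.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .containers import (
    MISSING,
    HaplotypePanel,
    Pedigree,
    TractSet,
    make_markers,
)


def read_vcf(path, region: str | None = None, allow_unphased: bool = False):
    """Read phased biallelic SNPs into a :class:`HaplotypePanel`.

    Multiallelic and indel records are skipped (their count is in the
    returned panel's nothing — see the second return value).  Unphased
    genotypes raise unless ``allow_unphased``; the panel's ``phased``
    flag then records that phase is unreliable.

    Returns (panel, n_skipped).
    """
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    chroms, poss, refs, alts = [], [], [], []
    hap_rows = []
    n_skipped = 0
    any_unphased = False
    it = vcf(region) if region else vcf
    for var in it:
        if len(var.ALT) != 1 or len(var.REF) != 1 or len(var.ALT[0]) != 1:
            n_skipped += 1
            continue
        if var.genotypes is None:
            raise ValueError(f"missing GT at {var.CHROM}:{var.POS}")
        col = np.empty((len(samples), 2), dtype=np.int8)
        for i, gt in enumerate(var.genotypes):
            a, b, phased = gt[0], gt[1], bool(gt[2])
            if a < 0 or b < 0:
                col[i] = MISSING
                continue
            if not phased:
                if not allow_unphased:
                    raise ValueError(
                        f"unphased genotype for {samples[i]} at {var.CHROM}:{var.POS}"
                    )
                any_unphased = True
            col[i, 0], col[i, 1] = a, b
        chroms.append(var.CHROM)
        poss.append(var.POS)
        refs.append(var.REF)
        alts.append(var.ALT[0])
        hap_rows.append(col)
    markers = make_markers(chroms, poss, refs, alts)
    haps = (
        np.stack(hap_rows, axis=2)
        if hap_rows
        else np.empty((len(samples), 2, 0), dtype=np.int8)
    )
    degraded = bool(np.any(haps == MISSING))
    panel = HaplotypePanel(
        markers, samples, haps, phased=not any_unphased, degraded=degraded
    )
    return panel, n_skipped


def write_vcf(panel: HaplotypePanel, path, contig_lengths: dict | None = None) -> None:
    """Write a panel as a minimal deterministic VCF 4.2 with GT only."""
    markers = panel.markers
    if contig_lengths is None:
        contig_lengths = {
            str(c): int(markers.loc[markers["chrom"] == c, "pos"].max())
            for c in markers["chrom"].unique()
        }
    sep = "|" if panel.phased else "/"
    lines = [
        "##fileformat=VCFv4.2",
        "##source=admixqc",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    ]
    for c, length in contig_lengths.items():
        lines.append(f"##contig=<ID={c},length={length}>")
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(panel.samples)
    )
    h = panel.haplotypes
    chrom_a = markers["chrom"].to_numpy()
    pos_a = markers["pos"].to_numpy()
    ref_a = markers["ref"].to_numpy()
    alt_a = markers["alt"].to_numpy()
    for m in range(panel.n_markers):
        gts = []
        for i in range(panel.n_samples):
            a, b = int(h[i, 0, m]), int(h[i, 1, m])
            gts.append("./." if a == MISSING or b == MISSING else f"{a}{sep}{b}")
        lines.append(
            f"{chrom_a[m]}\t{pos_a[m]}\t{chrom_a[m]}:{pos_a[m]}\t{ref_a[m]}\t{alt_a[m]}"
            f"\t.\tPASS\t.\tGT\t" + "\t".join(gts)
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def write_pedigree(pedigree: Pedigree, path) -> None:
    pedigree.table.to_csv(path, sep="\t", index=False)


def read_pedigree(path) -> Pedigree:
    tab = pd.read_csv(
        path, sep="\t", dtype={"id": str, "sire": str, "dam": str, "sex": str, "taxon": str}
    )
    return Pedigree(tab)


def write_tracts_bed(tracts: TractSet, path) -> None:
    """Truth tracts as tab-separated sample/hap/chrom/start/end/ancestry (0-based half-open)."""
    tab = tracts.tracts()[["sample", "hap", "chrom", "start", "end", "ancestry"]]
    tab.to_csv(path, sep="\t", index=False)


def read_tracts_bed(path, markers: pd.DataFrame) -> TractSet:
    """Read the BED-like tract format back onto a marker grid."""
    tab = pd.read_csv(path, sep="\t", dtype={"sample": str, "chrom": str})
    samples = list(dict.fromkeys(tab["sample"]))
    anc = np.full((len(samples), 2, len(markers)), -9, dtype=np.int8)
    pos = markers["pos"].to_numpy()
    chrom_a = markers["chrom"].to_numpy()
    sidx = {s: i for i, s in enumerate(samples)}
    for _, row in tab.iterrows():
        mk = (
            (chrom_a == row["chrom"])
            & (pos - 1 >= row["start"])
            & (pos - 1 < row["end"])
        )
        anc[sidx[row["sample"]], int(row["hap"]), mk] = int(row["ancestry"])
    if np.any(anc == -9):
        raise ValueError("tract file does not cover the marker grid")
    return TractSet(markers, samples, anc)


def write_global_ancestry(ancestry: pd.DataFrame, path) -> None:
    ancestry.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_config(path) -> dict:
    """Flat key=value config; '#' comments; values parsed as int/float/str."""
    out = {}
    with open(path) as fh:
        for ln in fh:
            ln = ln.split("#", 1)[0].strip()
            if not ln:
                continue
            if "=" not in ln:
                raise ValueError(f"malformed config line: {ln!r}")
            key, _, val = ln.partition("=")
            out[key.strip()] = _parse_scalar(val.strip())
    return out


def _parse_scalar(s: str):
    for cast in (int, float):
        try:
            return cast(s)
        except ValueError:
            pass
    return s
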