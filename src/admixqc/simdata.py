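"""Synthetic two-population pedigree simulator with ancestry-tract truth.

Emulates the statistical structure of a captive two-species colony:
two strongly differentiated founder populations (Balding-Nichols
divergence plus a fraction of fixed differences), purebred founders
drawn in Hardy-Weinberg proportions, multi-generation crosses with
Haldane (no-interference) recombination on a genetic map, optional
phase-switch injection and genotype-level missingness.  Every
simulated individual carries exact local-ancestry truth tracts.

All randomness flows through one :class:`numpy.random.Generator`
seeded per operation; identical seeds give identical outputs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import (
    MISSING,
    HaplotypePanel,
    Pedigree,
    PopulationFrequencies,
    TractSet,
    chrom_slices,
    make_markers,
)
from .genmap import GeneticMap

DEFAULT_CHROM_LENGTHS = {f"chr{i}": 50_000_000 for i in range(1, 5)}

_BASES = np.array(["A", "C", "G", "T"])


def simulate_founder_frequencies(
    n_markers: int,
    fst_target: float,
    fixed_fraction: float = 0.0,
    chrom_lengths: dict | None = None,
    seed: int = 0,
) -> PopulationFrequencies:
    """Draw per-population allele frequencies for two diverged populations.

    A ``fixed_fraction`` of markers is fixed for alternate alleles
    between the populations ((0,1) or (1,0) with equal probability).
    The remainder draw each population's frequency independently from a
    Balding-Nichols Beta distribution with divergence ``fst_target``
    around an ancestral frequency uniform on [0.05, 0.95].
    """
    if n_markers < 1:
        raise ValueError("n_markers must be >= 1")
    if not 0 < fst_target < 1:
        raise ValueError("fst_target must be in (0, 1)")
    if not 0 <= fixed_fraction <= 1:
        raise ValueError("fixed_fraction must be in [0, 1]")
    chrom_lengths = chrom_lengths or DEFAULT_CHROM_LENGTHS
    rng = np.random.default_rng(seed)

    chroms = list(chrom_lengths)
    lengths = np.array([chrom_lengths[c] for c in chroms], dtype=float)
    counts = rng.multinomial(n_markers, lengths / lengths.sum())
    chrom_col, pos_col = [], []
    for c, length, k in zip(chroms, lengths, counts):
        if k == 0:
            continue
        pos = np.sort(rng.choice(int(length), size=int(k), replace=False)) + 1
        chrom_col.extend([c] * int(k))
        pos_col.extend(pos.tolist())
    ref = _BASES[rng.integers(0, 4, size=n_markers)]
    alt = np.array([_BASES[(np.flatnonzero(_BASES == r)[0] + rng.integers(1, 4)) % 4] for r in ref])

    ancestral = rng.uniform(0.05, 0.95, size=n_markers)
    shape = (1.0 - fst_target) / fst_target
    freq = np.empty((n_markers, 2))
    for k in (0, 1):
        freq[:, k] = rng.beta(ancestral * shape, (1.0 - ancestral) * shape)

    n_fixed = int(round(fixed_fraction * n_markers))
    if n_fixed:
        fixed_idx = rng.choice(n_markers, size=n_fixed, replace=False)
        direction = rng.integers(0, 2, size=n_fixed)
        freq[fixed_idx, 0] = direction
        freq[fixed_idx, 1] = 1 - direction

    markers = make_markers(chrom_col, pos_col, ref, alt)
    return PopulationFrequencies(markers, freq, ancestral)


def _founder_ids(n_per_pop):
    names = []
    for pop, (tag, n) in enumerate(zip(("OLV", "YEL"), n_per_pop)):
        names.append([f"{tag}{i + 1:03d}" for i in range(n)])
    return names


def simulate_founders(
    freqs: PopulationFrequencies,
    n_per_pop=(9, 9),
    seed: int = 0,
) -> tuple[HaplotypePanel, Pedigree, TractSet]:
    """Draw purebred founders in Hardy-Weinberg proportions.

    Each haplotype allele is an independent Bernoulli draw from the
    founder's population frequency; truth tracts assign every marker to
    that population; the pedigree records founders at generation 0.
    """
    if freqs.n_markers == 0:
        raise ValueError("empty frequency table")
    if min(n_per_pop) < 1:
        raise ValueError("need at least one founder per population")
    rng = np.random.default_rng(seed)
    ids_by_pop = _founder_ids(n_per_pop)
    samples = ids_by_pop[0] + ids_by_pop[1]
    n = len(samples)
    m = freqs.n_markers

    haps = np.empty((n, 2, m), dtype=np.int8)
    anc = np.empty((n, 2, m), dtype=np.int8)
    row = 0
    ped_rows = []
    for pop, ids in enumerate(ids_by_pop):
        p = freqs.freq[:, pop]
        taxon = "olive" if pop == 0 else "yellow"
        for j, sid in enumerate(ids):
            haps[row] = (rng.random((2, m)) < p).astype(np.int8)
            anc[row] = pop
            ped_rows.append((sid, "0", "0", "M" if j % 2 == 0 else "F", taxon, 0))
            row += 1

    panel = HaplotypePanel(freqs.markers, samples, haps)
    pedigree = Pedigree(pd.DataFrame(ped_rows, columns=Pedigree.COLUMNS))
    truth = TractSet(freqs.markers, samples, anc)
    return panel, pedigree, truth


def _make_gamete(hap_pair, anc_pair, markers, gmap: GeneticMap, rng):
    """One recombined gamete (alleles, ancestry) from a parent's diplotype.

    Haldane model: crossover count per chromosome ~ Poisson(genetic
    length in Morgans), crossover points uniform on the cM scale,
    alternating parental haplotypes from a fair starting choice.
    """
    m = hap_pair.shape[1]
    alleles = np.empty(m, dtype=np.int8)
    ancestry = np.empty(m, dtype=np.int8)
    for chrom, sl in chrom_slices(markers):
        pos = markers["pos"].to_numpy()[sl]
        cm = gmap.interpolate(chrom, pos)
        cm0, cm1 = gmap.nodes[chrom][1][0], gmap.nodes[chrom][1][-1]
        length_m = (cm1 - cm0) / 100.0
        k = rng.poisson(length_m)
        current = int(rng.integers(0, 2))
        if k == 0:
            alleles[sl] = hap_pair[current, sl]
            ancestry[sl] = anc_pair[current, sl]
            continue
        xo_cm = np.sort(rng.uniform(cm0, cm1, size=k))
        # which haplotype each marker comes from: parity of crossovers to its left
        n_left = np.searchsorted(xo_cm, cm, side="right")
        source = (current + n_left) % 2
        idx = np.arange(sl.start, sl.stop)
        alleles[sl] = hap_pair[source, idx]
        ancestry[sl] = anc_pair[source, idx]
    return alleles, ancestry


def simulate_cross(
    parent1: str,
    parent2: str,
    panel: HaplotypePanel,
    truth: TractSet,
    gmap: GeneticMap,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Cross two panel samples; returns (haplotypes, ancestry), each (2, n_markers).

    Haplotype 0 is the gamete from ``parent1``, haplotype 1 from
    ``parent2``.
    """
    rng = np.random.default_rng(seed)
    for chrom in panel.markers["chrom"].unique():
        if chrom not in gmap.nodes:
            raise ValueError(f"genetic map does not cover chromosome {chrom}")
    i1, i2 = panel.sample_index(parent1), panel.sample_index(parent2)
    t1, t2 = truth.sample_index(parent1), truth.sample_index(parent2)
    h0, a0 = _make_gamete(panel.haplotypes[i1], truth.ancestry[t1], panel.markers, gmap, rng)
    h1, a1 = _make_gamete(panel.haplotypes[i2], truth.ancestry[t2], panel.markers, gmap, rng)
    return np.stack([h0, h1]), np.stack([a0, a1])


def simulate_pedigree(
    design: dict,
    freqs: PopulationFrequencies,
    gmap: GeneticMap,
    seed: int = 0,
) -> tuple[HaplotypePanel, Pedigree, TractSet]:
    """Simulate a full pedigree from a breeding design.

    ``design`` is a dict with keys ``founders`` (mapping "olive"/"yellow"
    to founder counts) and ``crosses`` (ordered list of (child id,
    sire id, dam id) tuples; parents must already exist).  Crosses are
    labelled taxon "cross" at generation max(parents) + 1.
    """
    rng = np.random.default_rng(seed)
    n_olive = design.get("founders", {}).get("olive", 0)
    n_yellow = design.get("founders", {}).get("yellow", 0)
    panel, pedigree, truth = simulate_founders(
        freqs, (n_olive, n_yellow), seed=int(rng.integers(2**31))
    )
    samples = list(panel.samples)
    haps = [panel.haplotypes[i] for i in range(len(samples))]
    ancs = [truth.ancestry[i] for i in range(len(samples))]
    ped_rows = [tuple(r) for r in pedigree.table.itertuples(index=False)]
    generation = {sid: 0 for sid in samples}

    for cross in design.get("crosses", []):
        child, sire, dam = cross[:3]
        if child in generation:
            raise ValueError(f"duplicate individual id {child!r} in design")
        for parent in (sire, dam):
            if parent not in generation:
                raise ValueError(f"cross {child!r} references unknown parent {parent!r}")
        sub_panel = HaplotypePanel(panel.markers, samples, np.stack(haps))
        sub_truth = TractSet(panel.markers, samples, np.stack(ancs))
        h, a = simulate_cross(sire, dam, sub_panel, sub_truth, gmap,
                              seed=int(rng.integers(2**31)))
        samples.append(child)
        haps.append(h)
        ancs.append(a)
        gen = max(generation[sire], generation[dam]) + 1
        generation[child] = gen
        sex = "M" if rng.integers(0, 2) == 0 else "F"
        ped_rows.append((child, sire, dam, sex, "cross", gen))

    out_panel = HaplotypePanel(panel.markers, samples, np.stack(haps))
    out_truth = TractSet(panel.markers, samples, np.stack(ancs))
    out_ped = Pedigree(pd.DataFrame(ped_rows, columns=Pedigree.COLUMNS))
    return out_panel, out_ped, out_truth


def simulate_admixed_panel(
    freqs: PopulationFrequencies,
    q_values,
    seed: int = 0,
) -> tuple[HaplotypePanel, TractSet]:
    """Admixed individuals with known global ancestry, no linkage structure.

    Each allele copy independently draws its ancestry ~ Bernoulli(1 - q)
    (q = olive proportion) and then its allele from that population's
    frequency.  Useful for calibrating marginal (per-marker) estimators;
    unlike pedigree simulation it produces no tract structure.
    """
    rng = np.random.default_rng(seed)
    q = np.asarray(q_values, dtype=float)
    n, m = len(q), freqs.n_markers
    anc = (rng.random((n, 2, m)) >= q[:, None, None]).astype(np.int8)  # 1 = yellow
    p = freqs.freq.T  # (2, m)
    haps = (rng.random((n, 2, m)) < p[anc, np.arange(m)]).astype(np.int8)
    samples = [f"ADM{i + 1:04d}" for i in range(n)]
    panel = HaplotypePanel(freqs.markers, samples, haps)
    truth = TractSet(freqs.markers, samples, anc)
    return panel, truth


def inject_phase_switches(
    panel: HaplotypePanel,
    truth: TractSet,
    rate: float | None = None,
    positions=None,
    gmap: GeneticMap | None = None,
    samples=None,
    seed: int = 0,
) -> tuple[HaplotypePanel, TractSet, pd.DataFrame]:
    """Swap haplotype suffixes at inter-marker boundaries (phase errors).

    Either ``rate`` (expected switches per Morgan, requires ``gmap``) or
    explicit ``positions`` — a list of (sample, chrom, boundary index)
    where the boundary index b (1 <= b < n_markers on that chromosome)
    swaps both haplotypes' alleles *and* truth ancestries from local
    marker b to the chromosome end.  Returns the modified copies and the
    ground-truth switch table (sample, chrom, boundary, pos).
    """
    if not panel.phased:
        raise ValueError("panel must be phased")
    if (rate is None) == (positions is None):
        raise ValueError("provide exactly one of rate or positions")
    out_panel = panel.copy()
    out_truth = truth.copy()
    slices = dict(chrom_slices(panel.markers))
    pos_all = panel.markers["pos"].to_numpy()

    if positions is None:
        if gmap is None:
            raise ValueError("rate mode requires a genetic map")
        rng = np.random.default_rng(seed)
        targets = samples if samples is not None else panel.samples
        positions = []
        for sample in targets:
            for chrom, sl in slices.items():
                n_local = sl.stop - sl.start
                if n_local < 2:
                    continue
                length_m = gmap.length_morgans(chrom)
                k = rng.poisson(rate * length_m)
                if k == 0:
                    continue
                cm_nodes = gmap.nodes[chrom][1]
                marker_cm = gmap.interpolate(chrom, pos_all[sl])
                xo = rng.uniform(cm_nodes[0], cm_nodes[-1], size=k)
                bounds = np.searchsorted(marker_cm, xo, side="right")
                # keep odd-multiplicity interior boundaries (pairs cancel)
                uniq, cnt = np.unique(bounds, return_counts=True)
                for b, c in zip(uniq, cnt):
                    if 1 <= b < n_local and c % 2 == 1:
                        positions.append((sample, chrom, int(b)))

    records = []
    for sample, chrom, b in positions:
        si = out_panel.sample_index(sample)
        sl = slices[chrom]
        n_local = sl.stop - sl.start
        if not 1 <= b < n_local:
            raise ValueError(f"boundary {b} outside marker range on {chrom}")
        g = sl.start + b
        out_panel.haplotypes[si, :, g:sl.stop] = out_panel.haplotypes[si, ::-1, g:sl.stop]
        ti = out_truth.sample_index(sample)
        out_truth.ancestry[ti, :, g:sl.stop] = out_truth.ancestry[ti, ::-1, g:sl.stop]
        records.append((sample, chrom, b, int(pos_all[g])))

    switches = pd.DataFrame(records, columns=["sample", "chrom", "boundary", "pos"])
    return out_panel, out_truth, switches


def degrade_genotypes(
    panel: HaplotypePanel,
    missing_rate: float,
    seed: int = 0,
) -> HaplotypePanel:
    """Mask genotypes (both haplotypes jointly) missing at ``missing_rate``."""
    if not 0 <= missing_rate < 1:
        raise ValueError("missing_rate must be in [0, 1)")
    out = panel.copy()
    if missing_rate == 0:
        return out
    rng = np.random.default_rng(seed)
    mask = rng.random((panel.n_samples, panel.n_markers)) < missing_rate
    out.haplotypes[np.broadcast_to(mask[:, None, :], out.haplotypes.shape)] = MISSING
    out.degraded = True
    return out
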