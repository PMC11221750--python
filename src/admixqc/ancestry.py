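"""Global and local two-way ancestry estimation.

Global ancestry uses the standard supervised admixture likelihood: the
two allele copies of each genotype are independent draws from the
mixture frequency q*p_olive + (1-q)*p_yellow, so the log-likelihood of
a sample's mixing proportion q is a sum of binomial terms over markers.
The likelihood is concave in q for fixed frequencies, so a bracketed
scalar maximizer finds the global optimum.  Unsupervised K=2 fitting
alternates that per-sample maximization with per-marker frequency
updates by expected allele counts.

Local ancestry uses a two-state hidden Markov model along each phased
haplotype: emissions are the (clamped) population allele frequencies
and the switch probability between consecutive markers at genetic
distance d Morgans is (1 - exp(-g*d)) times the prior of the other
state, with g the generations since admixture.  Decoding is Viterbi.
This is a deliberately simple stand-in for random-forest/CRF local
ancestry callers; their .msp.tsv output can be read directly instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .containers import (
    MISSING,
    HaplotypePanel,
    HmmConfig,
    PopulationFrequencies,
    TractSet,
    chrom_slices,
    make_markers,
)
from .genmap import GeneticMap

FREQ_CLAMP = 1e-4

GLOBAL_COLUMNS = ["sample", "q_olive", "q_yellow", "method", "n_used"]


def _loglik_q(q: float, g: np.ndarray, p0: np.ndarray, p1: np.ndarray) -> float:
    pm = q * p0 + (1.0 - q) * p1
    return float(np.sum(g * np.log(pm) + (2.0 - g) * np.log1p(-pm)))


def _maximize_q(g, p0, p1, tol=1e-6) -> float:
    res = minimize_scalar(
        lambda q: -_loglik_q(q, g, p0, p1),
        bounds=(0.0, 1.0), method="bounded", options={"xatol": tol},
    )
    best_q, best_ll = float(res.x), -float(res.fun)
    for q in (0.0, 1.0):  # bounded Brent cannot land exactly on the boundary
        ll = _loglik_q(q, g, p0, p1)
        if ll > best_ll:
            best_q, best_ll = q, ll
    return best_q


def estimate_admixture_supervised(
    dosages: np.ndarray,
    freqs: PopulationFrequencies,
    samples=None,
    tol: float = 1e-6,
) -> pd.DataFrame:
    """Supervised two-way global ancestry by per-sample likelihood maximization.

    ``dosages``: (n_samples, n_markers) alt-allele counts 0/1/2 with
    :data:`MISSING` for missing genotypes, aligned to ``freqs.markers``.
    Reference frequencies are clamped to [1e-4, 1 - 1e-4].  Returns a
    table (sample, q_olive, q_yellow, method, n_used).
    """
    dosages = np.atleast_2d(np.asarray(dosages))
    if dosages.shape[1] != freqs.n_markers:
        raise ValueError("dosage columns must align with frequency markers")
    p = np.clip(freqs.freq, FREQ_CLAMP, 1.0 - FREQ_CLAMP)
    if samples is None:
        samples = [f"S{i}" for i in range(dosages.shape[0])]
    rows = []
    for i, sid in enumerate(samples):
        g = dosages[i]
        ok = g != MISSING
        if not ok.any():
            raise ValueError(f"sample {sid!r} has no usable markers")
        q = _maximize_q(g[ok].astype(float), p[ok, 0], p[ok, 1], tol=tol)
        rows.append((sid, q, 1.0 - q, "likelihood", int(ok.sum())))
    return pd.DataFrame(rows, columns=GLOBAL_COLUMNS)


@dataclass
class UnsupervisedFit:
    """Result of the unsupervised K=2 fit."""

    ancestry: pd.DataFrame
    freqs: PopulationFrequencies
    converged: bool
    degenerate: bool
    n_iter: int
    loglik: float


def _total_loglik(dos, ok, q, p):
    ll = 0.0
    for i in range(dos.shape[0]):
        g = dos[i, ok[i]].astype(float)
        ll += _loglik_q(q[i], g, p[ok[i], 0], p[ok[i], 1])
    return ll


def estimate_admixture_unsupervised_k2(
    panel: HaplotypePanel,
    seed: int = 0,
    max_iter: int = 200,
    tol: float = 1e-6,
    labels: dict | None = None,
) -> UnsupervisedFit:
    """Unsupervised two-way admixture fit by block-coordinate ascent.

    Alternates (i) per-sample q maximization given the current cluster
    frequencies with (ii) per-marker frequency updates from expected
    allele counts given q, until the log-likelihood gain drops below
    ``tol`` or ``max_iter`` is reached.  Cluster labels are anchored so
    population 0 is the cluster with higher mean q among samples whose
    ``labels`` entry is "olive"; without labels, the first sample's
    majority cluster becomes population 0.  A fit whose two frequency
    vectors diverge no more than single-population sampling noise
    (pseudo-F_ST between the fitted clusters below 0.1) is flagged
    degenerate.
    """
    if panel.n_samples < 2:
        raise ValueError("need at least two samples")
    rng = np.random.default_rng(seed)
    dos = panel.dosages()
    ok = dos != MISSING
    n, m = dos.shape

    # initialise around the pooled frequency with symmetric jitter
    with np.errstate(invalid="ignore", divide="ignore"):
        pooled = np.where(ok, dos, 0).sum(axis=0) / (2.0 * ok.sum(axis=0))
    pooled = np.where(ok.sum(axis=0) > 0, pooled, 0.5)
    jitter = rng.uniform(0.05, 0.2, size=m)
    p = np.clip(
        np.stack([pooled + jitter, pooled - jitter], axis=1), FREQ_CLAMP, 1 - FREQ_CLAMP
    )
    q = rng.uniform(0.2, 0.8, size=n)

    last_ll = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # (i) per-sample q
        for i in range(n):
            g = dos[i, ok[i]].astype(float)
            q[i] = _maximize_q(g, p[ok[i], 0], p[ok[i], 1])
        # (ii) per-marker frequencies from expected allele counts
        d = np.where(ok, dos, 0).astype(float)
        qq = q[:, None]
        denom_alt = qq * p[:, 0] + (1 - qq) * p[:, 1]
        denom_ref = qq * (1 - p[:, 0]) + (1 - qq) * (1 - p[:, 1])
        w_alt0 = qq * p[:, 0] / denom_alt
        w_ref0 = qq * (1 - p[:, 0]) / denom_ref
        alt0 = (d * w_alt0 * ok).sum(axis=0)
        ref0 = ((2 - d) * w_ref0 * ok).sum(axis=0)
        alt1 = (d * (1 - w_alt0) * ok).sum(axis=0)
        ref1 = ((2 - d) * (1 - w_ref0) * ok).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p0_new = alt0 / (alt0 + ref0)
            p1_new = alt1 / (alt1 + ref1)
        p[:, 0] = np.clip(np.where(np.isfinite(p0_new), p0_new, p[:, 0]), FREQ_CLAMP, 1 - FREQ_CLAMP)
        p[:, 1] = np.clip(np.where(np.isfinite(p1_new), p1_new, p[:, 1]), FREQ_CLAMP, 1 - FREQ_CLAMP)

        ll = _total_loglik(dos, ok, q, p)
        if ll - last_ll < tol and it > 1:
            converged = True
            last_ll = ll
            break
        last_ll = ll

    # resolve label switching
    flip = False
    if labels:
        olive_idx = [i for i, s in enumerate(panel.samples) if labels.get(s) == "olive"]
        if olive_idx and np.mean(q[olive_idx]) < 0.5:
            flip = True
    elif q[0] < 0.5:
        flip = True
    if flip:
        q = 1.0 - q
        p = p[:, ::-1].copy()

    # degenerate when between-cluster divergence is within sampling noise of
    # one population: pseudo-F_ST of the fitted frequency vectors
    pbar = p.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        pseudo_fst = (p[:, 0] - p[:, 1]) ** 2 / (4 * pbar * (1 - pbar))
    degenerate = bool(np.nanmean(pseudo_fst) < 0.1)
    ancestry = pd.DataFrame(
        [
            (s, float(q[i]), float(1 - q[i]), "likelihood", int(ok[i].sum()))
            for i, s in enumerate(panel.samples)
        ],
        columns=GLOBAL_COLUMNS,
    )
    fitted = PopulationFrequencies(panel.markers, p, (p[:, 0] + p[:, 1]) / 2)
    return UnsupervisedFit(ancestry, fitted, converged, degenerate, it, last_ll)


def discover_purebreds(ancestry: pd.DataFrame, threshold: float = 0.99) -> dict:
    """Samples with > ``threshold`` ancestry in either population.

    Mirrors reference-panel discovery: returns {sample: 0 or 1}.
    """
    out = {}
    for _, row in ancestry.iterrows():
        if row["q_olive"] > threshold:
            out[row["sample"]] = 0
        elif row["q_yellow"] > threshold:
            out[row["sample"]] = 1
    return out


def hmm_local_ancestry(
    haplotype: np.ndarray,
    freqs: PopulationFrequencies,
    gmap: GeneticMap,
    cfg: HmmConfig | None = None,
) -> np.ndarray:
    """Viterbi path of per-marker ancestry codes for one phased haplotype.

    Missing alleles contribute no emission information.  Each
    chromosome is decoded independently, starting from the state prior.
    Returns an int8 array over markers; use
    :func:`hmm_local_ancestry_panel` for a cohort-level
    :class:`TractSet`.
    """
    cfg = cfg or HmmConfig()
    hap = np.asarray(haplotype)
    if hap.shape != (freqs.n_markers,):
        raise ValueError("haplotype length must equal marker count")
    p = np.clip(freqs.freq, cfg.error_floor, 1.0 - cfg.error_floor)
    prior = np.asarray(cfg.prior, dtype=float)
    path = np.empty(freqs.n_markers, dtype=np.int8)
    pos = freqs.markers["pos"].to_numpy()
    for chrom, sl in chrom_slices(freqs.markers):
        cm = np.asarray(gmap.interpolate(chrom, pos[sl]), dtype=float)
        path[sl] = _viterbi_two_state(hap[sl], p[sl], cm, prior, cfg.generations)
    return path


def _viterbi_two_state(hap, p, cm, prior, g) -> np.ndarray:
    m = len(hap)
    # log emission per state; missing alleles are uninformative
    with np.errstate(divide="ignore"):
        log_e = np.where(hap[:, None] == 1, np.log(p), np.log1p(-p))
    log_e[hap == MISSING] = 0.0

    d_morgans = np.diff(cm) / 100.0
    switch = -np.expm1(-g * d_morgans)  # 1 - exp(-g d) per boundary
    t01 = switch * prior[1]
    t10 = switch * prior[0]
    with np.errstate(divide="ignore"):
        l_stay0 = np.log1p(-t01)
        l_stay1 = np.log1p(-t10)
        l_sw01 = np.log(t01)
        l_sw10 = np.log(t10)

    e0 = log_e[:, 0].tolist()
    e1 = log_e[:, 1].tolist()
    d0 = float(np.log(prior[0])) + e0[0]
    d1 = float(np.log(prior[1])) + e1[0]
    back0 = np.empty(m, dtype=np.int8)
    back1 = np.empty(m, dtype=np.int8)
    s0, s1, w01, w10 = l_stay0.tolist(), l_stay1.tolist(), l_sw01.tolist(), l_sw10.tolist()
    for t in range(1, m):
        stay = d0 + s0[t - 1]
        come = d1 + w10[t - 1]
        if stay >= come:
            n0, back0[t] = stay, 0
        else:
            n0, back0[t] = come, 1
        stay = d1 + s1[t - 1]
        come = d0 + w01[t - 1]
        if stay >= come:
            n1, back1[t] = stay, 1
        else:
            n1, back1[t] = come, 0
        d0, d1 = n0 + e0[t], n1 + e1[t]
    path = np.empty(m, dtype=np.int8)
    path[-1] = 0 if d0 >= d1 else 1
    for t in range(m - 1, 0, -1):
        path[t - 1] = back0[t] if path[t] == 0 else back1[t]
    return path


def hmm_local_ancestry_panel(
    panel: HaplotypePanel,
    freqs: PopulationFrequencies,
    gmap: GeneticMap,
    cfg: HmmConfig | None = None,
) -> TractSet:
    """Decode local ancestry for every haplotype of every sample."""
    anc = np.empty_like(panel.haplotypes)
    for i in range(panel.n_samples):
        for hap in (0, 1):
            anc[i, hap] = hmm_local_ancestry(panel.haplotypes[i, hap], freqs, gmap, cfg)
    return TractSet(panel.markers, list(panel.samples), anc)


def global_from_tracts(tracts: TractSet) -> pd.DataFrame:
    """Global ancestry proportions from bp-length-weighted tracts.

    q_olive = total bp of ancestry-0 tracts over both haplotypes
    divided by twice the genome bp covered.
    """
    tab = tracts.tracts()
    if tab.empty:
        raise ValueError("empty tract set")
    tab = tab.assign(length=tab["end"] - tab["start"])
    rows = []
    for sample, grp in tab.groupby("sample", sort=False):
        total = grp["length"].sum()
        olive = grp.loc[grp["ancestry"] == 0, "length"].sum()
        q = olive / total
        rows.append((sample, float(q), float(1 - q), "tracts", int(total)))
    out = pd.DataFrame(rows, columns=GLOBAL_COLUMNS)
    # preserve the tract set's sample order
    order = {s: k for k, s in enumerate(tracts.samples)}
    return out.sort_values("sample", key=lambda s: s.map(order)).reset_index(drop=True)


def write_msp(tracts: TractSet, gmap: GeneticMap, path) -> None:
    """Write tracts in RFMix-v2 msp.tsv layout.

    One row per maximal segment over which every haplotype's ancestry
    is constant (segment boundaries are the union of all samples'
    tract boundaries); two columns per sample (hap 0, hap 1).
    """
    codes = sorted(tracts.codes.items())
    code_str = "\t".join(f"{name}={code}" for code, name in codes)
    header_cols = ["#chm", "spos", "epos", "sgpos", "egpos", "n snps"]
    for s in tracts.samples:
        header_cols += [f"{s}.0", f"{s}.1"]
    lines = [f"#Subpopulation order/codes: {code_str}", "\t".join(header_cols)]

    pos = tracts.markers["pos"].to_numpy()
    for chrom, sl in chrom_slices(tracts.markers):
        anc = tracts.ancestry[:, :, sl]  # (n, 2, m_local)
        p = pos[sl]
        flat = anc.reshape(-1, anc.shape[2])
        change = np.any(flat[:, 1:] != flat[:, :-1], axis=0)
        bounds = np.flatnonzero(change) + 1
        starts = np.concatenate([[0], bounds])
        ends = np.concatenate([bounds, [anc.shape[2]]])
        for a, b in zip(starts, ends):
            spos = int(p[a]) - 1
            epos = int(p[b]) - 1 if b < anc.shape[2] else int(p[-1])
            sg = float(gmap.interpolate(chrom, p[a]))
            eg = float(gmap.interpolate(chrom, p[b - 1]))
            row = [str(chrom), str(spos), str(epos), f"{sg:.5f}", f"{eg:.5f}", str(b - a)]
            for i in range(anc.shape[0]):
                row += [str(int(anc[i, 0, a])), str(int(anc[i, 1, a]))]
            lines.append("\t".join(row))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_msp(path, markers: pd.DataFrame | None = None) -> TractSet:
    """Read an RFMix-v2 msp.tsv file into a :class:`TractSet`.

    If ``markers`` is given, ancestry is assigned per marker by locating
    each position inside the msp segments (exact round-trip with
    :func:`write_msp` on the same grid).  Otherwise a minimal grid with
    one marker per segment start is synthesised.
    """
    with open(path) as fh:
        first = fh.readline().rstrip("\n")
        second = fh.readline().rstrip("\n")
        body = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not first.startswith("#Subpopulation order/codes:"):
        raise ValueError("malformed msp header line 1")
    codes = {}
    for tok in first.split(":", 1)[1].replace(",", " ").split():
        name, _, code = tok.partition("=")
        if not code:
            raise ValueError(f"malformed code token {tok!r}")
        codes[int(code)] = name
    cols = second.split("\t")
    if cols[:6] != ["#chm", "spos", "epos", "sgpos", "egpos", "n snps"]:
        raise ValueError("malformed msp header line 2")
    hap_cols = cols[6:]
    if len(hap_cols) % 2 != 0:
        raise ValueError("odd number of haplotype columns")
    samples = [c[:-2] for c in hap_cols[::2]]

    seg_chrom, seg_spos, seg_epos, seg_anc = [], [], [], []
    for ln in body:
        parts = ln.split("\t")
        if len(parts) != 6 + len(hap_cols):
            raise ValueError(f"ragged msp row: {ln[:50]!r}")
        seg_chrom.append(parts[0])
        seg_spos.append(int(parts[1]))
        seg_epos.append(int(parts[2]))
        anc_row = np.array([int(x) for x in parts[6:]], dtype=np.int8)
        if not set(anc_row.tolist()) <= set(codes):
            raise ValueError("unknown ancestry code in msp body")
        seg_anc.append(anc_row)
    seg_anc = np.array(seg_anc)  # (n_seg, 2*n_samples)

    if markers is None:
        markers = make_markers(seg_chrom, [s + 1 for s in seg_spos])
    n, m = len(samples), len(markers)
    anc = np.empty((n, 2, m), dtype=np.int8)
    chrom_arr = markers["chrom"].to_numpy()
    pos_arr = markers["pos"].to_numpy()
    seg_chrom = np.array(seg_chrom, dtype=object)
    for chrom in pd.unique(chrom_arr):
        seg_idx = np.flatnonzero(seg_chrom == chrom)
        if len(seg_idx) == 0:
            raise ValueError(f"no msp rows for chromosome {chrom}")
        mk = np.flatnonzero(chrom_arr == chrom)
        starts = np.array([seg_spos[k] for k in seg_idx])
        which = np.searchsorted(starts, pos_arr[mk] - 1, side="right") - 1
        which = np.clip(which, 0, len(seg_idx) - 1)
        rows = seg_anc[seg_idx[which]]  # (m_local, 2n)
        anc[:, 0, mk] = rows[:, 0::2].T
        anc[:, 1, mk] = rows[:, 1::2].T
    return TractSet(markers, samples, anc, codes={c: n_ for c, n_ in codes.items()})
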