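"""Differentiation statistics and ancestry-informative-marker selection.

Implements the Weir & Cockerham (1984) two-population diploid theta
estimator from its variance components a (among populations), b (among
individuals within populations) and c (within individuals), the
ratio-of-sums weighted genome-wide estimate, fixed-difference
enumeration, missingness/MAF marker filtering, pairwise dosage-r2 LD
pruning, and the four-stage AIM panel selection: F_ST threshold,
best-per-window binning, per-population strict LD pruning, and a final
merged pruning pass.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import MISSING, HaplotypePanel


def _pop_indices(panel: HaplotypePanel, pop_assignment) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(pop_assignment, dict):
        assign = np.array([pop_assignment.get(s, -1) for s in panel.samples])
    else:
        assign = np.asarray(pop_assignment)
    pops = sorted(set(assign[assign >= 0]))
    if pops != [0, 1]:
        raise ValueError("exactly two populations coded 0 and 1 are required")
    return np.flatnonzero(assign == 0), np.flatnonzero(assign == 1)


def wc_fst_per_marker(panel: HaplotypePanel, pop_assignment) -> pd.DataFrame:
    """Per-marker Weir-Cockerham theta for two diploid populations.

    Missing genotypes are excluded marker-wise.  A marker where either
    population has fewer than two usable diploids is flagged undefined
    (``defined`` False), as is a marker with non-positive denominator
    (both populations monomorphic for the same allele).

    Returns a DataFrame aligned to the panel's markers with columns
    num (a), den (a+b+c), fst, defined, n0, n1, p0, p1.
    """
    idx0, idx1 = _pop_indices(panel, pop_assignment)
    if len(idx0) < 2 or len(idx1) < 2:
        raise ValueError("each population needs at least two diploid samples")
    dos = panel.dosages()
    r = 2.0

    n = np.empty((2, panel.n_markers))
    p = np.empty((2, panel.n_markers))
    h = np.empty((2, panel.n_markers))
    for k, idx in enumerate((idx0, idx1)):
        d = dos[idx]
        ok = d != MISSING
        n[k] = ok.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p[k] = np.where(ok, d, 0).sum(axis=0) / (2.0 * n[k])
            h[k] = np.where(ok & (d == 1), 1, 0).sum(axis=0) / n[k]

    usable = (n[0] >= 2) & (n[1] >= 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        nbar = (n[0] + n[1]) / r
        nc = (n[0] + n[1] - (n[0] ** 2 + n[1] ** 2) / (n[0] + n[1])) / (r - 1)
        pbar = (n[0] * p[0] + n[1] * p[1]) / (r * nbar)
        s2 = (n[0] * (p[0] - pbar) ** 2 + n[1] * (p[1] - pbar) ** 2) / ((r - 1) * nbar)
        hbar = (n[0] * h[0] + n[1] * h[1]) / (r * nbar)

        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4.0) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2.0
        den = a + b + c
        fst = np.where(den > 0, a / np.where(den > 0, den, 1.0), np.nan)

    defined = usable & (den > 0)
    fst = np.where(defined, fst, np.nan)
    table = panel.markers.copy()
    table["num"] = np.where(usable, a, np.nan)
    table["den"] = np.where(usable, den, np.nan)
    table["fst"] = fst
    table["defined"] = defined
    table["n0"], table["n1"] = n[0], n[1]
    table["p0"], table["p1"] = p[0], p[1]
    return table


def weighted_fst(table: pd.DataFrame) -> float:
    """Ratio-of-sums weighted theta over markers with defined components."""
    ok = table["defined"].to_numpy()
    if not ok.any():
        raise ValueError("no defined markers")
    return float(table.loc[ok, "num"].sum() / table.loc[ok, "den"].sum())


def count_fixed_markers(table: pd.DataFrame) -> tuple[int, np.ndarray]:
    """Markers fixed for alternate alleles between the populations.

    A marker counts as fixed when the observed allele frequencies are
    exactly 0 in one population and 1 in the other (equivalently
    theta = 1 with no within-population variance).
    """
    if len(table) == 0:
        return 0, np.array([], dtype=int)
    p0 = table["p0"].to_numpy()
    p1 = table["p1"].to_numpy()
    usable = (table["n0"].to_numpy() >= 2) & (table["n1"].to_numpy() >= 2)
    fixed = usable & (((p0 == 0) & (p1 == 1)) | ((p0 == 1) & (p1 == 0)))
    idx = np.flatnonzero(fixed)
    return int(len(idx)), idx


def marker_missingness(panel: HaplotypePanel) -> np.ndarray:
    """Fraction of samples with a missing genotype, per marker."""
    return (panel.dosages() == MISSING).mean(axis=0)


def marker_maf(panel: HaplotypePanel) -> np.ndarray:
    """Minor-allele frequency per marker from non-missing genotypes.

    Markers with no usable genotypes get MAF 0.
    """
    dos = panel.dosages()
    ok = dos != MISSING
    n = ok.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(ok, dos, 0).sum(axis=0) / (2.0 * n)
    p = np.where(n > 0, p, 0.0)
    return np.minimum(p, 1.0 - p)


def filter_markers(
    panel: HaplotypePanel,
    max_missing: float = 0.0,
    min_maf: float = 0.05,
) -> np.ndarray:
    """Indices of markers passing missingness and MAF thresholds.

    Retains markers with missing-genotype fraction <= ``max_missing``
    and MAF >= ``min_maf``; order preserved.
    """
    keep = (marker_missingness(panel) <= max_missing) & (marker_maf(panel) >= min_maf)
    return np.flatnonzero(keep)


def ld_r2(panel: HaplotypePanel, i: int, j: int) -> float:
    """Squared Pearson correlation of diploid dosages at markers i and j.

    Complete-case over samples; 0 when either marker has zero variance;
    NaN (undefined) with fewer than two complete cases.
    """
    dos = panel.dosages()
    return _r2_from_dosage(dos[:, i], dos[:, j])


def _r2_from_dosage(x: np.ndarray, y: np.ndarray) -> float:
    ok = (x != MISSING) & (y != MISSING)
    if ok.sum() < 2:
        return float("nan")
    x = x[ok].astype(float)
    y = y[ok].astype(float)
    vx = x.var()
    vy = y.var()
    if vx == 0 or vy == 0:
        return 0.0
    cov = ((x - x.mean()) * (y - y.mean())).mean()
    return float(cov * cov / (vx * vy))


def ld_prune(
    panel: HaplotypePanel,
    markers=None,
    window: int = 50,
    step: int = 5,
    r2_max: float = 0.1,
) -> np.ndarray:
    """Greedy windowed LD pruning over a candidate marker list.

    Windows of ``window`` candidates advance by ``step``.  Within a
    window, while any surviving pair exceeds ``r2_max``, the pair member
    with the lower MAF is removed (MAF tie: the later-positioned
    member).  Pairs are examined in list order, so the procedure is
    deterministic.  Returns surviving marker indices (into the panel).
    """
    if window < 2:
        raise ValueError("window must be >= 2")
    cand = np.asarray(markers if markers is not None else np.arange(panel.n_markers))
    dos = panel.dosages()[:, cand].astype(np.float64)
    dos[dos == MISSING] = np.nan
    maf = marker_maf(panel)[cand]
    alive = np.ones(len(cand), dtype=bool)

    for w_start in range(0, max(len(cand) - 1, 1), step):
        w = [k for k in range(w_start, min(w_start + window, len(cand))) if alive[k]]
        changed = True
        while changed:
            changed = False
            for ai in range(len(w)):
                if changed:
                    break
                for bi in range(ai + 1, len(w)):
                    ki, kj = w[ai], w[bi]
                    if not (alive[ki] and alive[kj]):
                        continue
                    r2 = _r2_pair_nan(dos[:, ki], dos[:, kj])
                    if np.isnan(r2) or r2 <= r2_max:
                        continue
                    if maf[ki] < maf[kj]:
                        alive[ki] = False
                    elif maf[kj] < maf[ki]:
                        alive[kj] = False
                    else:
                        alive[kj] = False  # tie: drop the later-positioned
                    changed = True
                    break
            if changed:
                w = [k for k in w if alive[k]]
    return cand[alive]


def _r2_pair_nan(x: np.ndarray, y: np.ndarray) -> float:
    ok = ~(np.isnan(x) | np.isnan(y))
    if ok.sum() < 2:
        return float("nan")
    xs, ys = x[ok], y[ok]
    vx, vy = xs.var(), ys.var()
    if vx == 0 or vy == 0:
        return 0.0
    cov = ((xs - xs.mean()) * (ys - ys.mean())).mean()
    return float(cov * cov / (vx * vy))


@dataclass
class AimsPanel:
    """Selected ancestry-informative markers with selection provenance."""

    marker_index: np.ndarray  # indices into the source panel's markers
    fst: np.ndarray
    provenance: pd.DataFrame  # per stage-1 candidate: window id and survival flags

    def __len__(self):
        return len(self.marker_index)


def select_aims(
    table: pd.DataFrame,
    panel: HaplotypePanel,
    refs: tuple[list, list],
    fst_min: float = 0.8,
    window_bp: int = 100_000,
    pop_prune: tuple = (2, 1, 0.05),
) -> AimsPanel:
    """Four-stage AIM panel selection.

    1. Keep markers with defined F_ST strictly greater than ``fst_min``.
    2. Per non-overlapping ``window_bp`` window (anchored at coordinate
       0) per chromosome, keep the highest-F_ST marker; ties go to the
       first marker in input order.
    3. LD-prune the kept set within each reference population
       separately using ``pop_prune`` = (window, step, r2_max).
    4. Merge the two survivor sets and LD-prune once more on the pooled
       reference samples with the same parameters.
    """
    fst = table["fst"].to_numpy()
    defined = table["defined"].to_numpy()
    stage1 = np.flatnonzero(defined & (fst > fst_min))
    pos = table["pos"].to_numpy()
    chrom = table["chrom"].to_numpy()

    prov = pd.DataFrame({
        "marker": stage1,
        "chrom": chrom[stage1],
        "window": pos[stage1] // window_bp,
        "fst": fst[stage1],
        "stage2": False, "stage3": False, "stage4": False,
    })

    stage2 = []
    for _, grp in prov.groupby(["chrom", "window"], sort=False):
        best = grp["fst"].to_numpy().argmax()  # first max wins the tie
        stage2.append(grp["marker"].iloc[best])
    stage2 = np.array(sorted(stage2), dtype=int)
    prov.loc[prov["marker"].isin(stage2), "stage2"] = True

    w, s, r2 = pop_prune
    pooled = list(refs[0]) + list(refs[1])
    surv_by_pop = []
    for ref_samples in refs:
        sub = panel.subset_samples(list(ref_samples))
        surv_by_pop.append(set(ld_prune(sub, stage2, window=w, step=s, r2_max=r2)))
    merged = np.array(sorted(surv_by_pop[0] | surv_by_pop[1]), dtype=int)
    prov.loc[prov["marker"].isin(merged), "stage3"] = True

    final = ld_prune(panel.subset_samples(pooled), merged, window=w, step=s, r2_max=r2)
    prov.loc[prov["marker"].isin(final), "stage4"] = True

    final = np.array(sorted(final), dtype=int)
    return AimsPanel(final, fst[final], prov)
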