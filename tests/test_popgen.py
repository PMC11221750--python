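"""F_ST estimation, marker filtering, LD pruning and AIM selection."""

import numpy as np
import pandas as pd
import pytest

import admixqc as aq
from admixqc.containers import HaplotypePanel, make_markers
from admixqc.popgen import marker_maf


def panel_from_dosages(dosage_matrix, chrom=None, pos=None):
    """Build a panel whose genotypes realise the given dosage matrix."""
    d = np.asarray(dosage_matrix)
    n, m = d.shape
    haps = np.zeros((n, 2, m), dtype=np.int8)
    haps[:, 0, :] = np.where(d == aq.MISSING, aq.MISSING, (d >= 1).astype(int))
    haps[:, 1, :] = np.where(d == aq.MISSING, aq.MISSING, (d == 2).astype(int))
    markers = make_markers(
        chrom if chrom is not None else ["chr1"] * m,
        pos if pos is not None else np.arange(1, m + 1) * 1000,
    )
    return HaplotypePanel(
        markers, [f"S{i}" for i in range(n)], haps,
        degraded=bool(np.any(d == aq.MISSING)),
    )


def wc_theta_oracle(genotypes0, genotypes1):
    """Textbook two-population diploid variance components, coded per sample.

    Independent of the vectorised implementation: counts alleles and
    heterozygotes sample by sample from the genotype lists.
    """
    stats = []
    for geno in (genotypes0, genotypes1):
        geno = [g for g in geno if g != aq.MISSING]
        n = len(geno)
        p = sum(geno) / (2 * n)
        h = sum(1 for g in geno if g == 1) / n
        stats.append((n, p, h))
    (n1, p1, h1), (n2, p2, h2) = stats
    r = 2
    nbar = (n1 + n2) / r
    nc = (n1 + n2 - (n1 * n1 + n2 * n2) / (n1 + n2)) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / (n1 + n2)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (n1 + n2)
    a = nbar / nc * (s2 - 1 / (nbar - 1) * (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4))
    b = nbar / (nbar - 1) * (pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar)
    c = hbar / 2
    return a, a + b + c


ASSIGN_4_4 = {f"S{i}": (0 if i < 4 else 1) for i in range(8)}


class TestWcFst:
    def test_fixed_difference_gives_exactly_one(self):
        d = np.vstack([np.zeros((9, 5)), np.full((9, 5), 2)])
        panel = panel_from_dosages(d)
        assign = {f"S{i}": (0 if i < 9 else 1) for i in range(18)}
        table = aq.wc_fst_per_marker(panel, assign)
        assert np.all(table["fst"].to_numpy() == 1.0)

    def test_jointly_monomorphic_marker_is_undefined(self):
        d = np.zeros((8, 3))
        table = aq.wc_fst_per_marker(panel_from_dosages(d), ASSIGN_4_4)
        assert not table["defined"].any()
        assert table["fst"].isna().all()

    def test_matches_independent_variance_component_oracle(self):
        rng = np.random.default_rng(50)
        d = rng.integers(0, 3, size=(8, 40))
        table = aq.wc_fst_per_marker(panel_from_dosages(d), ASSIGN_4_4)
        for m in range(40):
            a, den = wc_theta_oracle(d[:4, m].tolist(), d[4:, m].tolist())
            if den <= 0:
                assert not table["defined"].iloc[m]
                continue
            assert table["num"].iloc[m] == pytest.approx(a, abs=1e-12)
            assert table["den"].iloc[m] == pytest.approx(den, abs=1e-12)
            assert table["fst"].iloc[m] == pytest.approx(a / den, abs=1e-12)

    def test_missing_genotypes_excluded_marker_wise(self):
        d = np.array([[2, 2], [2, aq.MISSING], [0, 0], [0, 0],
                      [0, 0], [0, 2], [0, 0], [0, 0]])
        table = aq.wc_fst_per_marker(panel_from_dosages(d), ASSIGN_4_4)
        a, den = wc_theta_oracle([2, 0, 0], [0, 2, 0, 0])
        assert table["n0"].iloc[1] == 3
        if den > 0:
            assert table["fst"].iloc[1] == pytest.approx(a / den, abs=1e-12)

    def test_population_with_one_usable_sample_flags_marker(self):
        d = np.array([[2, aq.MISSING, aq.MISSING, aq.MISSING, 0, 0, 0, 0]]).T
        table = aq.wc_fst_per_marker(panel_from_dosages(d), ASSIGN_4_4)
        assert not table["defined"].iloc[0]

    def test_fewer_than_two_populations_rejected(self):
        panel = panel_from_dosages(np.zeros((4, 2)))
        with pytest.raises(ValueError):
            aq.wc_fst_per_marker(panel, {f"S{i}": 0 for i in range(4)})


class TestWeightedFst:
    def test_single_defined_marker_equals_its_estimate(self):
        d = np.array([[2, 2, 1, 1, 0, 0, 0, 1]]).T
        table = aq.wc_fst_per_marker(panel_from_dosages(d), ASSIGN_4_4)
        assert aq.weighted_fst(table) == pytest.approx(table["fst"].iloc[0])

    def test_all_fixed_different_gives_one(self):
        d = np.vstack([np.full((4, 6), 2), np.zeros((4, 6))])
        table = aq.wc_fst_per_marker(panel_from_dosages(d), ASSIGN_4_4)
        assert aq.weighted_fst(table) == pytest.approx(1.0)

    def test_invariant_to_marker_order(self):
        rng = np.random.default_rng(51)
        d = rng.integers(0, 3, size=(8, 30))
        table = aq.wc_fst_per_marker(panel_from_dosages(d), ASSIGN_4_4)
        shuffled = table.sample(frac=1, random_state=1)
        assert aq.weighted_fst(shuffled) == pytest.approx(aq.weighted_fst(table), abs=1e-15)

    def test_all_undefined_rejected(self):
        table = aq.wc_fst_per_marker(panel_from_dosages(np.zeros((8, 2))), ASSIGN_4_4)
        with pytest.raises(ValueError):
            aq.weighted_fst(table)


class TestFixedMarkers:
    def test_count_matches_brute_force_frequency_scan(self, founder_sim):
        panel, _, _ = founder_sim
        assign = {s: (0 if s.startswith("OLV") else 1) for s in panel.samples}
        table = aq.wc_fst_per_marker(panel, assign)
        count, idx = aq.count_fixed_markers(table)
        d = panel.dosages()
        olive = np.array([assign[s] == 0 for s in panel.samples])
        brute = []
        for m in range(panel.n_markers):
            f0 = d[olive, m].mean() / 2
            f1 = d[~olive, m].mean() / 2
            if {f0, f1} == {0.0, 1.0}:
                brute.append(m)
        assert count == len(brute)
        assert np.array_equal(idx, np.array(brute))
        assert count > 0  # the generator seeds some fixed differences

    def test_all_fixed_input_counts_everything(self):
        d = np.vstack([np.full((4, 7), 2), np.zeros((4, 7))])
        table = aq.wc_fst_per_marker(panel_from_dosages(d), ASSIGN_4_4)
        assert aq.count_fixed_markers(table)[0] == 7

    def test_empty_table(self):
        assert aq.count_fixed_markers(pd.DataFrame())[0] == 0


class TestFilterMarkers:
    def test_low_maf_marker_removed(self):
        d = np.zeros((10, 2), dtype=int)
        d[0, 0] = 1  # MAF 0.05 at marker 0 -> retained at threshold 0.05
        panel = panel_from_dosages(d)
        kept = aq.filter_markers(panel, max_missing=0.0, min_maf=0.05)
        assert 0 in kept and 1 not in kept

    def test_zero_missing_threshold_removes_any_missing(self):
        d = np.array([[1, 1], [1, aq.MISSING], [1, 1], [1, 1]])
        kept = aq.filter_markers(panel_from_dosages(d), max_missing=0.0, min_maf=0.0)
        assert list(kept) == [0]

    def test_fully_typed_half_frequency_marker_always_retained(self):
        d = np.array([[0], [2], [0], [2]])
        kept = aq.filter_markers(panel_from_dosages(d), max_missing=0.0, min_maf=0.5)
        assert list(kept) == [0]


class TestLdR2:
    def test_identical_dosage_vectors_give_one(self):
        d = np.column_stack([[0, 1, 2, 1, 0, 2]] * 2)
        assert aq.ld_r2(panel_from_dosages(d), 0, 1) == pytest.approx(1.0)

    def test_monomorphic_marker_gives_zero_by_convention(self):
        d = np.column_stack([[1, 1, 1, 1], [0, 1, 2, 1]])
        assert aq.ld_r2(panel_from_dosages(d), 0, 1) == 0.0

    def test_matches_direct_correlation_oracle(self):
        rng = np.random.default_rng(52)
        d = rng.integers(0, 3, size=(6, 8))
        panel = panel_from_dosages(d)
        for i, j in [(0, 1), (2, 5), (3, 7)]:
            r = np.corrcoef(d[:, i], d[:, j])[0, 1]
            assert aq.ld_r2(panel, i, j) == pytest.approx(r * r, abs=1e-12)

    def test_fewer_than_two_complete_cases_is_undefined(self):
        d = np.array([[0, aq.MISSING], [aq.MISSING, 1], [1, aq.MISSING]])
        assert np.isnan(aq.ld_r2(panel_from_dosages(d), 0, 1))


def ld_prune_oracle(dosage, cand, window, step, r2_max, maf):
    """Exhaustive greedy pruning oracle on a tiny instance."""
    alive = {k: True for k in range(len(cand))}
    start = 0
    while start < max(len(cand) - 1, 1):
        changed = True
        while changed:
            changed = False
            w = [k for k in range(start, min(start + window, len(cand))) if alive[k]]
            for x in range(len(w)):
                for y in range(x + 1, len(w)):
                    i, j = w[x], w[y]
                    xi, xj = dosage[:, cand[i]].astype(float), dosage[:, cand[j]].astype(float)
                    if xi.var() == 0 or xj.var() == 0:
                        continue
                    r2 = np.corrcoef(xi, xj)[0, 1] ** 2
                    if r2 > r2_max:
                        drop = i if maf[cand[i]] < maf[cand[j]] else (
                            j if maf[cand[j]] < maf[cand[i]] else j)
                        alive[drop] = False
                        changed = True
                        break
                if changed:
                    break
        start += step
    return [cand[k] for k in range(len(cand)) if alive[k]]


class TestLdPrune:
    def test_two_perfectly_correlated_adjacent_markers_leave_one(self):
        d = np.column_stack([[0, 1, 2, 1, 0], [0, 1, 2, 1, 0]])
        surv = aq.ld_prune(panel_from_dosages(d), window=2, step=1, r2_max=0.05)
        assert len(surv) == 1

    def test_mutually_independent_markers_all_survive(self):
        rng = np.random.default_rng(53)
        d = rng.integers(0, 3, size=(40, 6))
        panel = panel_from_dosages(d)
        surv = aq.ld_prune(panel, window=6, step=1, r2_max=0.99)
        assert len(surv) == 6

    def test_matches_exhaustive_greedy_oracle_on_small_instances(self):
        rng = np.random.default_rng(54)
        for trial in range(10):
            d = rng.integers(0, 3, size=(8, 10))
            panel = panel_from_dosages(d)
            maf = marker_maf(panel)
            cand = list(range(10))
            for window, step, r2m in [(2, 1, 0.05), (4, 2, 0.3), (10, 1, 0.5)]:
                got = sorted(aq.ld_prune(panel, cand, window=window, step=step, r2_max=r2m))
                want = sorted(ld_prune_oracle(d, cand, window, step, r2m, maf))
                assert got == want, (trial, window, step, r2m)

    def test_window_below_two_rejected(self):
        with pytest.raises(ValueError):
            aq.ld_prune(panel_from_dosages(np.zeros((4, 3))), window=1)


class TestSelectAims:
    def _table_and_panel(self, fsts, positions, n=8):
        d = np.vstack([np.full((4, len(fsts)), 2), np.zeros((4, len(fsts)))])
        rng = np.random.default_rng(55)
        panel = panel_from_dosages(
            rng.integers(0, 3, size=(8, len(fsts))), pos=positions
        )
        table = panel.markers.copy()
        table["fst"] = fsts
        table["defined"] = True
        return table, panel

    def test_no_markers_above_threshold_gives_empty_panel(self):
        table, panel = self._table_and_panel([0.5, 0.8, 0.7], [100, 200, 300])
        sel = aq.select_aims(table, panel, (["S0", "S1", "S2"], ["S4", "S5", "S6"]))
        assert len(sel) == 0

    def test_highest_fst_marker_wins_the_window(self):
        table, panel = self._table_and_panel([0.9, 0.95], [100, 200])
        sel = aq.select_aims(table, panel, (["S0", "S1"], ["S4", "S5"]))
        assert list(panel.markers.iloc[sel.marker_index]["pos"]) == [200]

    def test_fst_tie_keeps_first_marker_in_input_order(self):
        table, panel = self._table_and_panel([0.9, 0.9], [100, 200])
        sel = aq.select_aims(table, panel, (["S0", "S1"], ["S4", "S5"]))
        assert list(panel.markers.iloc[sel.marker_index]["pos"]) == [100]

    def test_one_marker_per_window_and_threshold_is_strict(self, founder_sim):
        panel, _, _ = founder_sim
        assign = {s: (0 if s.startswith("OLV") else 1) for s in panel.samples}
        table = aq.wc_fst_per_marker(panel, assign)
        refs0 = [s for s in panel.samples if s.startswith("OLV")]
        refs1 = [s for s in panel.samples if s.startswith("YEL")]
        sel = aq.select_aims(table, panel, (refs0, refs1))
        assert len(sel) > 0
        assert np.all(sel.fst > 0.8)
        mk = panel.markers.iloc[sel.marker_index]
        windows = mk.assign(w=mk["pos"] // 100_000).groupby(["chrom", "w"]).size()
        assert (windows <= 1).all()
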