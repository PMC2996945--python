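"""AIM selection, VIF pruning, random panels and panel summaries."""

import itertools

import numpy as np
import pandas as pd
import pytest

import aimpanel as ap
from aimpanel.io_formats import GeneticMapTable, GenotypeDataset, MISSING
from aimpanel.panel_select import (SelectionConfig, genotype_r2, panel_summary,
                                   random_panel, select_aims, vif_prune)
from oracles import brute_force_select, brute_force_vif_prune


class TestGenotypeR2:
    def test_identical_vectors(self):
        g = np.array([0, 1, 2, 1, 0, 2])
        assert genotype_r2(g, g) == pytest.approx(1.0)

    def test_perfect_negative_correlation(self):
        g = np.array([0, 1, 2, 1, 0, 2])
        assert genotype_r2(g, 2 - g) == pytest.approx(1.0)

    def test_hand_computed_value(self):
        x = np.array([0, 1, 2, 2, 1, 0], dtype=float)
        y = np.array([1, 1, 2, 0, 2, 0], dtype=float)
        cov = ((x - x.mean()) * (y - y.mean())).mean()
        expected = (cov / (x.std() * y.std())) ** 2
        assert genotype_r2(x, y) == pytest.approx(expected, abs=1e-12)

    def test_constant_vector_convention(self):
        assert genotype_r2(np.ones(6), np.array([0, 1, 2, 0, 1, 2])) == 0.0

    def test_pairwise_complete_only(self):
        x = np.array([0, 1, 2, MISSING, 1, 0])
        y = np.array([0, 1, 2, 2, MISSING, 0])
        ok = (x != MISSING) & (y != MISSING)
        expected = genotype_r2(x[ok], y[ok])
        assert genotype_r2(x, y) == pytest.approx(expected)

    def test_too_few_complete_pairs(self):
        with pytest.raises(Exception):
            genotype_r2(np.array([0, MISSING, MISSING]),
                        np.array([MISSING, 1, 1]))


class TestSelectAims:
    def test_single_qualifying_snp(self, small_cohort):
        p1, p2 = small_cohort["pop1"], small_cohort["pop2"]
        one1 = p1.subset_snps(p1.snp_ids[:1])
        one2 = p2.subset_snps(p2.snp_ids[:1])
        panel = select_aims(one1, one2, SelectionConfig(threshold=0.3))
        assert panel.snp_ids == p1.snp_ids[:1]

    def test_conflicting_pair_loses_smaller_delta(self):
        # two bin-top SNPs, duplicate genotypes in parent1 (r2 = 1), delta
        # 0.8 vs 0.7, nothing left in the losing bin -> panel of size 1
        from aimpanel.io_formats import SnpRecord, make_snp_table
        rng = np.random.default_rng(0)
        n = 200
        snps = make_snp_table([
            SnpRecord("hi", "1", 500_000, "A", "C", 0.5),
            SnpRecord("lo", "1", 1_500_000, "A", "C", 1.5)])
        g = rng.binomial(1, 0.5, size=n)
        # parent1: same column twice -> r2 = 1; parent2 independent
        calls1 = np.column_stack([g + rng.binomial(1, 0.9, n),
                                  g + rng.binomial(1, 0.9, n)]).astype(np.int8)
        calls1 = np.clip(calls1, 0, 2)
        calls1[:, 1] = calls1[:, 0]
        calls2 = rng.binomial(2, [0.1, 0.2], size=(n, 2)).astype(np.int8)
        p1 = GenotypeDataset([f"a{i}" for i in range(n)], snps, calls1)
        p2 = GenotypeDataset([f"b{i}" for i in range(n)], snps, calls2)
        d1 = np.abs(calls1[:, 0].mean() / 2 - calls2[:, 0].mean() / 2)
        d2 = np.abs(calls1[:, 1].mean() / 2 - calls2[:, 1].mean() / 2)
        panel = select_aims(p1, p2, SelectionConfig(threshold=0.3))
        winner = "hi" if round(d1, 4) >= round(d2, 4) else "lo"
        assert len(panel) == 1
        assert panel.snp_ids == [winner]

    def test_matches_brute_force_oracle(self, ld_fixture):
        p1, p2 = ld_fixture
        cfg = SelectionConfig(criterion="delta", threshold=0.6,
                              bin_size_bp=1_000_000, r2_max=0.4, maf_min=0.01)
        panel = select_aims(p1, p2, cfg)
        expected = brute_force_select(p1, p2, "delta", 0.6, 1_000_000, 0.4,
                                      0.01)
        assert panel.snp_ids == expected

    def test_matches_brute_force_oracle_fst(self, ld_fixture):
        p1, p2 = ld_fixture
        cfg = SelectionConfig(criterion="fst", threshold=0.4)
        panel = select_aims(p1, p2, cfg)
        expected = brute_force_select(p1, p2, "fst", 0.4, 1_000_000, 0.4, 0.01)
        assert panel.snp_ids == expected

    def test_final_panel_r2_invariant(self, ld_fixture):
        p1, p2 = ld_fixture
        panel = select_aims(p1, p2)
        ids = {s: i for i, s in enumerate(p1.snp_ids)}
        for chrom, grp in panel.table.groupby("chromosome"):
            for a, b in itertools.combinations(grp["snp_id"], 2):
                assert genotype_r2(p1.calls[:, ids[a]],
                                   p1.calls[:, ids[b]]) < 0.4
                assert genotype_r2(p2.calls[:, ids[a]],
                                   p2.calls[:, ids[b]]) < 0.4

    def test_one_snp_per_bin_and_threshold(self, ld_fixture):
        p1, p2 = ld_fixture
        panel = select_aims(p1, p2)
        assert (panel.table["delta"] >= 0.6).all()
        keys = list(zip(panel.table["chromosome"], panel.table["bin_index"]))
        assert len(keys) == len(set(keys))

    def test_threshold_monotonicity(self, ld_fixture):
        p1, p2 = ld_fixture
        sizes = [len(select_aims(p1, p2, SelectionConfig(threshold=t)))
                 for t in (0.60, 0.65, 0.70, 0.75)]
        assert sizes == sorted(sizes, reverse=True)

    def test_deterministic(self, ld_fixture):
        p1, p2 = ld_fixture
        a = select_aims(p1, p2)
        b = select_aims(p1, p2)
        assert a.snp_ids == b.snp_ids

    def test_no_ld_panel_is_per_bin_argmax(self):
        cfg = ap.SimConfig(n_individuals=50, n_snps=120,
                           chromosome_lengths_cm=(30.0, 30.0), seed=21,
                           n_ref=200)
        p1, p2, _ = ap.simulate_parental(cfg)
        panel = select_aims(p1, p2)
        stats = ap.differentiation_table(p1, p2)
        delta = stats.set_index("snp_id")["delta"]
        bins = {}
        for row in p1.snps.itertuples():
            d = delta[row.snp_id]
            maf_ok = True
            for ds in (p1, p2):
                f = ds.allele_frequencies()[p1.snp_ids.index(row.snp_id)]
                maf_ok &= min(f, 1 - f) >= 0.01
            if d >= 0.6 and maf_ok:
                key = (row.chromosome, (row.position_bp - 1) // 1_000_000)
                if key not in bins or d > bins[key][0]:
                    bins[key] = (d, row.snp_id)
        if panel.n_iterations == 0:  # fixture has no planted LD
            assert sorted(panel.snp_ids) == sorted(v[1] for v in bins.values())

    def test_empty_candidate_set(self, small_cohort):
        p1, p2 = small_cohort["pop1"], small_cohort["pop2"]
        panel = select_aims(p1, p2, SelectionConfig(threshold=1.0))
        assert len(panel) == 0


class TestVifPrune:
    def _dataset(self, calls):
        import aimpanel.simulate as sim
        cfg = ap.SimConfig(n_individuals=calls.shape[0],
                           n_snps=calls.shape[1],
                           chromosome_lengths_cm=(60.0,), seed=5)
        return GenotypeDataset([f"s{i}" for i in range(calls.shape[0])],
                               sim._snp_positions(cfg),
                               calls.astype(np.int8))

    def test_independent_snps_all_retained(self):
        rng = np.random.default_rng(8)
        calls = rng.binomial(2, 0.5, size=(200, 30))
        ds = self._dataset(calls)
        assert vif_prune(ds, window_snps=10, slide_snps=3,
                         vif_max=1.5) == ds.snp_ids

    def test_duplicate_column_loses_exactly_one_copy(self):
        rng = np.random.default_rng(9)
        calls = rng.binomial(2, 0.5, size=(100, 10))
        calls[:, 4] = calls[:, 3]
        ds = self._dataset(calls)
        # vif_max 1.5 leaves chance correlations alone; only the exact
        # duplicate (infinite VIF) goes
        kept = vif_prune(ds, window_snps=10, slide_snps=5, vif_max=1.5)
        assert len(kept) == 9
        assert ds.snp_ids[3] in kept
        assert ds.snp_ids[4] not in kept

    def test_matches_windowed_brute_force(self):
        rng = np.random.default_rng(10)
        calls = rng.binomial(2, 0.5, size=(150, 60)).astype(float)
        # planted 3-SNP linear dependency
        calls[:, 20] = np.clip(np.round((calls[:, 18] + calls[:, 19]) / 2), 0, 2)
        ds = self._dataset(calls)
        kept = vif_prune(ds, window_snps=15, slide_snps=5, vif_max=1.1)
        expected = brute_force_vif_prune(ds, 15, 5, 1.1)
        assert kept == expected


class TestRandomPanel:
    def test_full_fraction(self):
        ids = [f"r{i}" for i in range(10)]
        assert random_panel(ids, 1.0, seed=1) == ids

    def test_seed_reproducibility(self):
        ids = [f"r{i}" for i in range(1000)]
        assert random_panel(ids, 0.3, 42) == random_panel(ids, 0.3, 42)
        assert random_panel(ids, 0.3, 42) != random_panel(ids, 0.3, 43)

    def test_rounding_convention(self):
        ids = [f"r{i}" for i in range(21_637)]
        assert len(random_panel(ids, 0.1, 0)) == 2164


class TestPanelSummary:
    def _panel(self, cms, bps, chrom="1"):
        table = pd.DataFrame({
            "snp_id": [f"m{i}" for i in range(len(cms))],
            "chromosome": chrom, "position_bp": bps, "position_cm": cms,
            "allele_ref": "A", "allele_alt": "C",
            "p_pop1": 0.9, "p_pop2": 0.1, "delta": 0.8, "fst": 0.64,
            "sic": 0.3, "bin_index": range(len(cms))})
        return ap.AimPanel(table=table, criterion="delta", threshold=0.6)

    def test_simple_gap(self):
        out = panel_summary(self._panel([1.0, 4.0], [1_000_000, 4_000_000]))
        assert out.mean_gap_cm == pytest.approx(3.0)
        assert out.n_markers == 2

    def test_centromere_straddling_gap_excluded(self):
        cen = pd.DataFrame({"chrom": ["1"], "start": [2_000_000],
                            "end": [3_000_000]})
        out = panel_summary(self._panel([1.0, 4.0], [1_000_000, 4_000_000]),
                            centromeres=cen)
        assert out.mean_gap_cm is None
        assert out.n_gaps_included == 0

    def test_matches_gap_enumeration(self, ld_fixture):
        p1, p2 = ld_fixture
        panel = select_aims(p1, p2)
        out = panel_summary(panel)
        gaps = []
        for _, grp in panel.table.groupby("chromosome"):
            cm = grp.sort_values("position_bp")["position_cm"].to_numpy()
            gaps.extend(np.diff(cm))
        assert out.mean_gap_cm == pytest.approx(np.mean(gaps))
        assert out.per_chromosome["n_markers"].sum() == len(panel)
        assert out.mean_delta == pytest.approx(panel.table["delta"].mean())
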