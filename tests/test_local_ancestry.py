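"""Local-ancestry HMM: oracle equivalence, fitting, map power."""

import numpy as np
import pandas as pd
import pytest

import aimpanel as ap
from aimpanel.io_formats import GenotypeDataset, SnpRecord, make_snp_table
from aimpanel.local_ancestry import (AdmixtureHMM, AdmixtureModelParams,
                                     effective_sample_factor, fit_admixture,
                                     make_grid, map_power, marker_posteriors,
                                     posterior_field,
                                     power_threshold_fractions)
from oracles import enumerate_posteriors


def _single_snp_dataset(genotype, p_ceu, p_yri):
    snps = make_snp_table([SnpRecord("s0", "1", 1, "A", "C", 0.0),
                           SnpRecord("s1", "1", 100_000_000, "A", "C", 100.0)])
    # second marker is missing so the first drives the posterior alone
    calls = np.array([[genotype, -1]], dtype=np.int8)
    freqs = pd.DataFrame({"snp_id": ["s0", "s1"],
                          "p_ceu": [p_ceu, 0.5], "p_yri": [p_yri, 0.5]})
    return GenotypeDataset(["i0"], snps, calls), freqs


class TestPosteriors:
    def test_uninformative_emission_returns_prior(self):
        ds, freqs = _single_snp_dataset(1, 0.4, 0.4)
        m = 0.3
        params = AdmixtureModelParams(np.array([m]), 7.0, freqs)
        field = marker_posteriors(ds, params)
        np.testing.assert_allclose(
            field.q[0, 0], [(1 - m) ** 2, 2 * m * (1 - m), m ** 2],
            atol=1e-12)

    def test_fully_informative_marker(self):
        ds, freqs = _single_snp_dataset(2, 1.0, 0.0)
        params = AdmixtureModelParams(np.array([0.3]), 7.0, freqs)
        field = marker_posteriors(ds, params)
        assert field.q[0, 0, 2] > 0.999

    def test_two_linked_snps_match_enumeration(self):
        snps = make_snp_table([SnpRecord("a", "1", 1, "A", "C", 0.0),
                               SnpRecord("b", "1", 5_000_001, "A", "C", 5.0)])
        calls = np.array([[2, 0]], dtype=np.int8)
        freqs = pd.DataFrame({"snp_id": ["a", "b"],
                              "p_ceu": [0.9, 0.8], "p_yri": [0.1, 0.3]})
        ds = GenotypeDataset(["i0"], snps, calls)
        params = AdmixtureModelParams(np.array([0.25]), 6.0, freqs)
        field = marker_posteriors(ds, params)
        oracle = enumerate_posteriors(calls[0], np.array([0.0, 5.0]),
                                      freqs["p_ceu"], freqs["p_yri"],
                                      params.m[0], 6.0)
        np.testing.assert_allclose(field.q[0], oracle, atol=1e-10)

    def test_five_loci_with_missing_match_enumeration(self, tiny_hmm_problem):
        t = tiny_hmm_problem
        params = AdmixtureModelParams(t["m"], t["lambda_gen"], t["freqs"])
        field = marker_posteriors(t["dataset"], params)
        for i in range(2):
            oracle = enumerate_posteriors(
                t["dataset"].calls[i], t["cm"], t["freqs"]["p_ceu"],
                t["freqs"]["p_yri"], params.m[i], t["lambda_gen"])
            assert np.abs(field.q[i] - oracle).max() < 1e-8

    def test_grid_points_match_augmented_enumeration(self, tiny_hmm_problem):
        t = tiny_hmm_problem
        params = AdmixtureModelParams(t["m"], t["lambda_gen"], t["freqs"])
        grid_cm = [1.0, 10.0, 22.0]
        grid = pd.DataFrame({"chromosome": "1", "position_cm": grid_cm})
        field = posterior_field(t["dataset"], params, grid=grid)
        cm_aug = np.sort(np.concatenate([t["cm"], grid_cm]))
        where = {c: k for k, c in enumerate(cm_aug)}
        for i in range(2):
            calls_aug = np.full(len(cm_aug), -1)
            pc = np.full(len(cm_aug), 0.5)
            py = np.full(len(cm_aug), 0.5)
            for j, c in enumerate(t["cm"]):
                calls_aug[where[c]] = t["dataset"].calls[i, j]
                pc[where[c]] = t["freqs"]["p_ceu"][j]
                py[where[c]] = t["freqs"]["p_yri"][j]
            oracle = enumerate_posteriors(calls_aug, cm_aug, pc, py,
                                          params.m[i], t["lambda_gen"])
            got = field.q[i]
            exp = oracle[[where[c] for c in grid_cm]]
            assert np.abs(got - exp).max() < 1e-8

    def test_posterior_rows_normalized(self, small_cohort):
        truth = small_cohort["truth"]
        params = AdmixtureModelParams(truth.m, 7.0, small_cohort["freqs"])
        field = posterior_field(small_cohort["admixed"], params,
                                grid_spacing_cm=25.0)
        np.testing.assert_allclose(field.q.sum(axis=2), 1.0, atol=1e-9)


class TestTractLengthEffect:
    def test_higher_lambda_decorrelates_neighboring_loci(self):
        cfg = ap.SimConfig(n_individuals=60, n_snps=80,
                           chromosome_lengths_cm=(150.0,), seed=13)
        _, _, freqs = ap.simulate_parental(cfg)
        adm, truth = ap.simulate_admixed(cfg, freqs)
        corr = {}
        for lam in (2.0, 30.0):
            params = AdmixtureModelParams(truth.m, lam, freqs)
            field = marker_posteriors(adm, params)
            k = field.mean_k()
            d = k - k.mean(axis=0)
            # mean correlation between adjacent marker posteriors
            num = (d[:, :-1] * d[:, 1:]).mean()
            den = d[:, :-1].std() * d[:, 1:].std()
            corr[lam] = num / den
        assert corr[30.0] < corr[2.0]


class TestFit:
    def test_boundary_recovery_all_african(self):
        cfg = ap.SimConfig(n_individuals=20, n_snps=300, m_beta=(1e-6, 1.0),
                           chromosome_lengths_cm=(200.0, 200.0), seed=31)
        _, _, freqs = ap.simulate_parental(cfg)
        adm, truth = ap.simulate_admixed(cfg, freqs)
        assert truth.m.max() < 1e-3
        res = fit_admixture(adm, freqs, fit_lambda=False, max_iter=30)
        assert res.m_hat.max() <= 0.01

    def test_marker_order_invariance(self, small_cohort):
        ds = small_cohort["admixed"]
        freqs = small_cohort["freqs"]
        res1 = fit_admixture(ds, freqs, fit_lambda=False, max_iter=10)
        res2 = fit_admixture(ds, freqs.sample(frac=1.0, random_state=0),
                             fit_lambda=False, max_iter=10)
        np.testing.assert_allclose(res1.m_hat, res2.m_hat, atol=1e-12)

    def test_likelihood_improves_net(self, small_cohort):
        res = fit_admixture(small_cohort["admixed"], small_cohort["freqs"],
                            fit_lambda=False, max_iter=25)
        path = res.loglik_path
        assert path[-1] > path[0]
        assert path[1] >= path[0]  # first fixed-point step always ascends

    def test_results_summary_mentions_estimates(self, small_cohort):
        res = fit_admixture(small_cohort["admixed"], small_cohort["freqs"],
                            fit_lambda=False, max_iter=10)
        text = res.summary()
        assert "European ancestry" in text
        assert f"{res.model.dataset.n_samples}" in text


class TestMapPower:
    def _params(self, n=4, m=0.2):
        return AdmixtureModelParams(np.full(n, m), 7.0,
                                    pd.DataFrame({"snp_id": [], "p_ceu": [],
                                                  "p_yri": []}))

    def _field(self, q):
        q = np.asarray(q, float)
        grid = pd.DataFrame({"chromosome": "1",
                             "position_cm": np.arange(q.shape[1], dtype=float)})
        samples = [f"s{i}" for i in range(q.shape[0])]
        from aimpanel.local_ancestry import AncestryPosteriorField
        return AncestryPosteriorField(samples, grid, q)

    def test_posteriors_equal_priors_give_zero(self):
        params = self._params()
        prior = params.prior_k()
        q = np.repeat(prior[:, None, :], 5, axis=1)
        result = map_power(self._field(q), params)
        np.testing.assert_allclose(result.r_i, 0.0, atol=1e-12)

    def test_degenerate_posteriors_give_one(self):
        params = self._params()
        q = np.zeros((4, 5, 3))
        q[:, :, 2] = 1.0
        result = map_power(self._field(q), params)
        np.testing.assert_allclose(result.r_i, 1.0)
        assert result.r_avg == 1.0

    def test_boundary_admixture_rejected(self):
        params = self._params(n=3)
        params.m = np.zeros(3)  # force past the constructor clamp
        q = np.zeros((3, 2, 3))
        q[:, :, 0] = 1.0
        with pytest.raises(Exception, match="undefined"):
            map_power(self._field(q), params)

    def test_effective_sample_factor_published_values(self):
        assert effective_sample_factor(0.73) == 1.37
        assert effective_sample_factor(0.65) == 1.54
        assert effective_sample_factor(1.0) == 1.0
        with pytest.raises(Exception):
            effective_sample_factor(0.0)

    def test_threshold_fractions_count(self):
        params = self._params()
        q = np.zeros((4, 4, 3))
        q[:, :, 2] = 1.0
        res = map_power(self._field(q), params)
        res.r_i = np.array([1.0, 0.6, 0.6, 0.3])
        fracs = power_threshold_fractions(res)
        assert fracs[0.50] == pytest.approx(0.75)
        assert fracs[0.75] == pytest.approx(0.25)
        assert fracs[0.80] == pytest.approx(0.25)
        # direct counting oracle
        for t, f in fracs.items():
            assert f == (res.r_i >= t).sum() / len(res.r_i)


def test_denser_panels_increase_r_avg(small_cohort):
    ds = small_cohort["admixed"]
    truth = small_cohort["truth"]
    params = AdmixtureModelParams(truth.m, 7.0, small_cohort["freqs"])
    grid = make_grid(ds, 20.0)
    r = []
    for step in (4, 2, 1):
        sub = ds.subset_snps(ds.snp_ids[::step])
        field = posterior_field(sub, params, grid=grid)
        r.append(map_power(field, params).r_avg)
    assert r[0] < r[1] < r[2]
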