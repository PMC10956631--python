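"""Covariate screen, per-pair OLS, permutation null, beta MLE, empirical
p-values, BH FDR, threshold and call rules."""

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats

from eqthm.preprocess import estimate_5hmc
from eqthm.scan import (CollinearityError, bh_fdr, call_eqthms,
                        empirical_pvalue, empirical_threshold, fit_beta_mle,
                        fit_cis_model, permutation_null, run_scan,
                        screen_covariates)
from eqthm.simulate import simulate_dataset
from eqthm.config import SynthConfig
from eqthm.annotate import build_cis_pairs


def ols_oracle(y, X):
    """From-scratch normal equations + t CDF, independent of fit_cis_model."""
    xtx = X.T @ X
    beta = np.linalg.solve(xtx, X.T @ y)
    resid = y - X @ beta
    df = len(y) - X.shape[1]
    sigma2 = resid @ resid / df
    cov = sigma2 * np.linalg.inv(xtx)
    se = np.sqrt(cov[1, 1])
    t = beta[1] / se
    p = 2 * (1 - stats.t.cdf(abs(t), df))
    return beta[1], se, t, p


class TestFitCisModel:
    def test_exact_fit(self):
        hm = np.arange(10.0)
        beta1, se, t, p = fit_cis_model(2.0 * hm, hm)
        assert beta1 == pytest.approx(2.0, abs=1e-12)
        assert se == pytest.approx(0.0, abs=1e-12)
        assert p < 1e-100   # exact fit up to float rounding

    def test_matches_normal_equations_oracle(self, rng):
        for _ in range(200):
            n = int(rng.integers(10, 40))
            hm = rng.normal(size=n)
            T = rng.normal(size=(n, 3))
            y = rng.normal(size=n) + 0.5 * hm + T @ rng.normal(size=3)
            got = fit_cis_model(y, hm, T)
            X = np.column_stack([np.ones(n), hm, T])
            want = ols_oracle(y, X)
            np.testing.assert_allclose(got, want, rtol=0, atol=1e-10)

    def test_collinear_design_names_columns(self, rng):
        hm = rng.normal(size=20)
        with pytest.raises(CollinearityError, match="covariate"):
            fit_cis_model(rng.normal(size=20), hm, np.column_stack([hm, hm]))

    def test_null_pvalues_roughly_uniform(self, rng):
        ps = []
        for _ in range(300):
            y = rng.normal(size=50)
            hm = rng.normal(size=50)
            ps.append(fit_cis_model(y, hm)[3])
        assert stats.kstest(ps, "uniform").pvalue > 1e-3


class TestPermutationNull:
    def _setup(self, seed=0):
        cfg = SynthConfig(n_samples=60, n_genes=8, n_cpgs=120,
                          chrom_length=3_000_000, n_true_eqthm=0,
                          n_true_dhmr=0, seed=seed)
        d = simulate_dataset(cfg)
        m = estimate_5hmc(d.betas).m_values
        pairs = build_cis_pairs(d.cpgs, d.genes, 300_000)
        return d, m, pairs

    def test_output_shape_and_determinism(self):
        d, m, pairs = self._setup()
        a = permutation_null(d.expression, m, None, pairs, n_perm=25, seed=9)
        b = permutation_null(d.expression, m, None, pairs, n_perm=25, seed=9)
        assert a.shape == (pairs["gene_id"].nunique(), 25)
        pd.testing.assert_frame_equal(a, b)
        c = permutation_null(d.expression, m, None, pairs, n_perm=25, seed=10)
        assert not np.allclose(a.to_numpy(), c.to_numpy())

    def test_single_cpg_gene_minima_are_uniform(self):
        # under a global null, the min over 1 CpG is the nominal p itself
        d, m, pairs = self._setup(seed=3)
        one = pairs.groupby("gene_id").head(1)
        res = permutation_null(d.expression, m, None, one, n_perm=200, seed=1)
        vals = res.to_numpy().ravel()
        assert np.mean(vals) == pytest.approx(0.5, abs=3 * 0.289 / np.sqrt(len(vals)) + 0.02)

    def test_joint_covariate_shuffle_variant_runs_and_differs(self):
        d, m, pairs = self._setup(seed=5)
        cov = d.covariates.astype(float)
        a = permutation_null(d.expression, m, cov, pairs, n_perm=20, seed=3)
        b = permutation_null(d.expression, m, cov, pairs, n_perm=20, seed=3,
                             shuffle_covariates=True)
        assert a.shape == b.shape
        assert not np.allclose(a.to_numpy(), b.to_numpy())

    def test_too_few_permutations_rejected(self):
        d, m, pairs = self._setup()
        with pytest.raises(ValueError):
            permutation_null(d.expression, m, None, pairs, n_perm=1)


class TestBetaMle:
    def test_uniform_sample_recovers_one_one(self):
        x = np.random.default_rng(0).uniform(size=10_000)
        a, b = fit_beta_mle(x)
        assert 0.95 <= a <= 1.05 and 0.95 <= b <= 1.05

    def test_skewed_parameter_recovery(self):
        x = np.random.default_rng(1).beta(0.5, 20.0, size=10_000)
        a, b = fit_beta_mle(np.clip(x, 1e-12, 1 - 1e-12))
        assert a == pytest.approx(0.5, rel=0.10)
        assert b == pytest.approx(20.0, rel=0.10)

    def test_likelihood_never_below_moment_start(self, rng):
        for _ in range(20):
            x = rng.beta(rng.uniform(0.3, 3), rng.uniform(1, 30), size=500)
            x = np.clip(x, 1e-12, 1 - 1e-12)
            a, b = fit_beta_mle(x)
            m, v = x.mean(), x.var()
            c = m * (1 - m) / v - 1
            a0, b0 = max(m * c, 1e-3), max((1 - m) * c, 1e-3)

            def ll(aa, bb):
                return np.sum(stats.beta.logpdf(x, aa, bb))

            assert ll(a, b) >= ll(a0, b0) - 1e-9

    def test_degenerate_input_rejected(self):
        with pytest.raises(ValueError):
            fit_beta_mle(np.full(100, 0.3))
        with pytest.raises(ValueError):
            fit_beta_mle([0.1] * 5)


class TestEmpiricalPvalue:
    def test_cdf_endpoints(self):
        assert empirical_pvalue(0.0, 2.0, 5.0) == 0.0
        assert empirical_pvalue(1.0, 2.0, 5.0) == 1.0

    def test_uniform_identity(self):
        x = np.linspace(0, 1, 11)
        np.testing.assert_allclose(empirical_pvalue(x, 1.0, 1.0), x, atol=1e-12)

    def test_matches_quadrature_oracle(self):
        a, b = 2.0, 50.0
        expected, _ = integrate.quad(lambda u: stats.beta.pdf(u, a, b), 0, 0.01)
        assert empirical_pvalue(0.01, a, b) == pytest.approx(expected, rel=1e-8)

    def test_monotone_in_observed_minimum(self):
        x = np.linspace(0, 1, 200)
        v = empirical_pvalue(x, 1.7, 33.0)
        assert np.all(np.diff(v) >= 0)


class TestBhFdr:
    def test_hand_stepup(self):
        np.testing.assert_allclose(bh_fdr([0.005, 0.05, 0.5]),
                                   [0.015, 0.075, 0.5], atol=1e-12)

    def test_constant_vector_unchanged(self):
        np.testing.assert_allclose(bh_fdr([0.2, 0.2, 0.2]), [0.2] * 3)

    def test_dominates_raw_p(self, rng):
        p = rng.uniform(size=50)
        q = bh_fdr(p)
        assert np.all(q >= p - 1e-15)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-15)


class TestThresholdAndCalls:
    def _nulls(self, p_emp):
        return pd.DataFrame({"gene_id": [f"g{i}" for i in range(len(p_emp))],
                             "p_empirical": p_emp, "q_bh": bh_fdr(p_emp)})

    def test_hand_worked_threshold(self):
        nulls = self._nulls([0.001, 0.01, 0.04, 0.2])
        np.testing.assert_allclose(nulls["q_bh"],
                                   [0.004, 0.02, 0.05333333, 0.2], atol=1e-6)
        assert empirical_threshold(nulls) == pytest.approx(0.01)

    def test_single_significant_gene(self):
        nulls = self._nulls([0.01])
        assert empirical_threshold(nulls) == pytest.approx(0.01)

    def test_no_significant_gene_returns_sentinel(self):
        nulls = self._nulls([0.2, 0.5, 0.9])
        assert empirical_threshold(nulls) is None

    def test_call_rule_requires_both_conditions(self):
        assoc = pd.DataFrame({
            "cpg_id": ["c1", "c2"], "gene_id": ["g1", "g2"],
            "p_nominal": [0.005, 0.005]})
        nulls = pd.DataFrame({"gene_id": ["g1", "g2"],
                              "p_empirical": [0.01, 0.06],
                              "q_bh": [0.02, 0.08]})
        m = pd.DataFrame(np.random.default_rng(0).normal(size=(2, 30)),
                         index=["c1", "c2"])
        y = pd.DataFrame(np.random.default_rng(1).normal(size=(2, 30)),
                         index=["g1", "g2"])
        out = call_eqthms(assoc, nulls, 0.01, m, y)
        assert out.set_index("cpg_id")["is_eqthm"].tolist() == [True, False]
        assert np.isfinite(out.loc[out["is_eqthm"], "r"]).all()

    def test_beta_inverted_rule_agrees_with_literal_for_uniform_null(self):
        # with a Beta(1,1) null the inverted per-gene threshold equals pt
        assoc = pd.DataFrame({"cpg_id": ["c1"], "gene_id": ["g1"],
                              "p_nominal": [0.004]})
        nulls = pd.DataFrame({"gene_id": ["g1"], "p_empirical": [0.004],
                              "q_bh": [0.004], "a": [1.0], "b": [1.0]})
        m = pd.DataFrame(np.random.default_rng(0).normal(size=(1, 20)),
                         index=["c1"])
        y = pd.DataFrame(np.random.default_rng(1).normal(size=(1, 20)),
                         index=["g1"])
        lit = call_eqthms(assoc, nulls, 0.01, m, y, rule="literal")
        inv = call_eqthms(assoc, nulls, 0.01, m, y, rule="beta-inverted")
        assert lit["is_eqthm"].tolist() == inv["is_eqthm"].tolist() == [True]

    def test_planted_pair_correlation_sign_matches_effect(self):
        cfg = SynthConfig(n_samples=120, n_genes=10, n_cpgs=200,
                          chrom_length=4_000_000, n_true_eqthm=3,
                          n_true_dhmr=0, cov_h_strength=0.0,
                          cov_expr_strength=0.0, seed=21)
        d = simulate_dataset(cfg)
        m = estimate_5hmc(d.betas).m_values
        pairs = build_cis_pairs(d.cpgs, d.genes)
        res = run_scan(m, d.expression, None, pairs, n_perm=100, seed=2)
        hits = res.eqthms.merge(d.truth.pairs, on=["cpg_id", "gene_id"])
        assert len(hits) > 0
        assert (np.sign(hits["r"]) == np.sign(hits["beta1_y"])).all()


class TestRunScanInternals:
    def test_scan_statistics_match_full_ols(self):
        cfg = SynthConfig(n_samples=50, n_genes=6, n_cpgs=80,
                          chrom_length=3_000_000, n_true_eqthm=1,
                          n_true_dhmr=0, seed=13)
        d = simulate_dataset(cfg)
        m = estimate_5hmc(d.betas).m_values
        pairs = build_cis_pairs(d.cpgs, d.genes, 200_000)
        cov = d.covariates.astype(float)
        res = run_scan(m, d.expression, cov, pairs, n_perm=10, seed=0)
        sub = res.associations.sample(15, random_state=0)
        for row in sub.itertuples(index=False):
            y = d.expression.loc[row.gene_id].to_numpy()
            hm = m.loc[row.cpg_id].to_numpy()
            b1, se, t, p = fit_cis_model(y, hm, cov.to_numpy())
            assert row.beta1 == pytest.approx(b1, abs=1e-9)
            assert row.se == pytest.approx(se, abs=1e-9)
            assert row.p_nominal == pytest.approx(p, abs=1e-9)


class TestScreenCovariates:
    def _shared_factor_data(self, n=80, seed=0):
        r = np.random.default_rng(seed)
        factor = r.normal(size=n)
        m = pd.DataFrame(np.outer(r.normal(size=40), factor)
                         + 0.1 * r.normal(size=(40, n)))
        e = pd.DataFrame(np.outer(r.normal(size=30), factor)
                         + 0.1 * r.normal(size=(30, n)))
        m.columns = e.columns = [f"S{i}" for i in range(n)]
        return m, e, factor

    def test_candidate_equal_to_shared_pc_selected(self):
        m, e, factor = self._shared_factor_data()
        cands = pd.DataFrame({"good": factor}, index=m.columns)
        assert screen_covariates(m, e, cands) == ["good"]

    def test_and_rule_rejects_one_sided_candidate(self):
        r = np.random.default_rng(1)
        n = 80
        factor_e = r.normal(size=n)
        m = pd.DataFrame(r.normal(size=(40, n)), columns=[f"S{i}" for i in range(n)])
        e = pd.DataFrame(np.outer(r.normal(size=30), factor_e)
                         + 0.05 * r.normal(size=(30, n)), columns=m.columns)
        cands = pd.DataFrame({"exp_only": factor_e}, index=m.columns)
        assert screen_covariates(m, e, cands) == []

    def test_zero_variance_candidate_skipped_with_warning(self):
        m, e, factor = self._shared_factor_data()
        cands = pd.DataFrame({"flat": np.ones(len(factor))}, index=m.columns)
        with pytest.warns(UserWarning, match="zero variance"):
            assert screen_covariates(m, e, cands) == []

    def test_noise_candidate_selection_rate_is_calibrated(self):
        # two independent alpha=0.05 screens => selection rate near
        # (1-(1-.05)^5)^2 ~ 0.05 for an unrelated candidate
        hits = 0
        reps = 200
        for i in range(reps):
            r = np.random.default_rng(100 + i)
            m = pd.DataFrame(r.normal(size=(25, 40)))
            e = pd.DataFrame(r.normal(size=(20, 40)))
            m.columns = e.columns = [f"S{j}" for j in range(40)]
            cands = pd.DataFrame({"noise": r.normal(size=40)}, index=m.columns)
            hits += len(screen_covariates(m, e, cands))
        assert 0.005 <= hits / reps <= 0.13
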