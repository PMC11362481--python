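"""Maximum-likelihood estimation: closed forms, oracles, invariances."""

import numpy as np
import pytest

import sempower as sp
from sempower import datagen, ml_estimator
from sempower.errors import DegeneracyError, InvalidParameterError


class TestSampleCov:
    def test_two_point_hand_computation(self):
        s = sp.sample_cov(np.array([[0.0, 0.0], [2.0, 2.0]]))
        assert np.allclose(s, [[1.0, 1.0], [1.0, 1.0]])

    def test_matches_brute_force_definition(self, rng):
        x = rng.standard_normal((37, 5))
        xbar = x.mean(axis=0)
        brute = sum(np.outer(r - xbar, r - xbar) for r in x) / len(x)
        assert np.allclose(sp.sample_cov(x), brute, atol=1e-12)

    def test_single_observation_rejected(self):
        with pytest.raises(InvalidParameterError):
            sp.sample_cov(np.ones((1, 3)))

    def test_constant_column_warns(self):
        x = np.column_stack([np.ones(10), np.arange(10.0)])
        with pytest.warns(UserWarning):
            sp.sample_cov(x)


class TestDiscrepancy:
    def test_zero_iff_equal(self):
        s = np.array([[1.0, 0.3], [0.3, 1.0]])
        assert sp.fml(s, s) == pytest.approx(0.0, abs=1e-14)
        assert sp.fml(np.eye(2), np.eye(2)) == 0.0

    def test_scalar_closed_form(self):
        # p=1: F = ln(sigma) - ln(s) + s/sigma - 1
        assert sp.fml([[2.0]], [[1.0]]) == pytest.approx(1.0 - np.log(2.0), abs=1e-12)
        assert sp.fml([[2.0]], [[1.0]]) == pytest.approx(0.30685, abs=5e-6)

    def test_nonnegative_on_random_pairs(self, rng):
        for _ in range(20):
            a = rng.standard_normal((4, 8))
            b = rng.standard_normal((4, 8))
            assert sp.fml(a @ a.T / 8, b @ b.T / 8) >= 0.0

    def test_singular_model_covariance_rejected(self):
        with pytest.raises(DegeneracyError):
            sp.fml(np.eye(2), np.ones((2, 2)))


class TestFit:
    def test_self_consistency_recovers_population(self, patterns, tripartite_pop):
        """Fitting the generating pattern to its own Σ gives F=0 and θ̂=θ0."""
        sigma = sp.implied_covariance(tripartite_pop).sigma
        fr = sp.fit_cov(patterns[3], sigma, 200)
        assert fr.converged and fr.admissible
        assert fr.F_ml < 1e-8
        pm = ml_estimator._ParamMap(patterns[3])
        lam, phi, th = pm.unpack(fr.estimates)
        assert np.allclose(np.abs(lam), tripartite_pop.loadings, atol=1e-4)
        assert np.allclose(phi, tripartite_pop.factor_cov, atol=1e-4)
        assert np.allclose(th, tripartite_pop.residuals, atol=1e-4)

    def test_just_identified_single_factor_closed_form(self):
        """p=3 one-factor model: λ̂_1 = sqrt(s12·s13/s23) etc., T = 0, df = 0."""
        spec = sp.parse_model("f =~ x1 + x2 + x3\n")
        s = np.array([[1.0, 0.48, 0.42], [0.48, 1.0, 0.56], [0.42, 0.56, 1.0]])
        fr = sp.fit_cov(spec, s, 100)
        assert fr.converged
        assert fr.df == 0
        assert fr.T == pytest.approx(0.0, abs=1e-6)
        lam = np.sort(np.abs(fr.estimates[:3]))
        assert np.allclose(lam, [0.6, 0.7, 0.8], atol=1e-5)

    def test_parameter_recovery_at_large_n(self, patterns, tripartite_pop):
        data = sp.generate(tripartite_pop, 10_000, 42)
        fr = sp.fit(patterns[3], data)
        assert fr.converged
        pm = ml_estimator._ParamMap(patterns[3])
        lam, phi, th = pm.unpack(fr.estimates)
        assert np.abs(np.abs(lam[tripartite_pop.loading_pattern])
                      - tripartite_pop.loadings[tripartite_pop.loading_pattern]).max() < 0.03
        assert np.abs(phi - tripartite_pop.factor_cov).max() < 0.03

    def test_optimum_beats_random_admissible_draws(self):
        """Stochastic global-minimum oracle on small random instances."""
        rng = np.random.default_rng(77)
        for _ in range(25):
            p = int(rng.integers(3, 7))
            m = 1 if p < 5 else int(rng.integers(1, 3))
            lines = []
            for j in range(m):
                inds = [f"x{i}" for i in range(p) if i % m == j or rng.random() < 0.3]
                lines.append(f"f{j} =~ " + " + ".join(inds))
            spec = sp.parse_model("\n".join(lines))
            try:
                df = sp.model_df(spec)
            except sp.UnderIdentifiedError:
                continue
            x = rng.standard_normal((60, p))
            s = sp.sample_cov(x)
            fr = sp.fit_cov(spec, s, 60)
            if not fr.converged:
                continue
            pm = ml_estimator._ParamMap(spec)
            best_random = np.inf
            for _ in range(1000):
                theta = rng.uniform(-1, 1, pm.q)
                theta[pm.nl + pm.np_:] = rng.uniform(0.05, 2.0, pm.nr)
                lam, phi, th = pm.unpack(theta)
                sigma = lam @ phi @ lam.T + np.diag(th)
                if np.linalg.eigvalsh(sigma)[0] <= 1e-8:
                    continue
                best_random = min(best_random, sp.fml(s, sigma))
            assert fr.F_ml <= best_random + 1e-8

    def test_agrees_with_statsmodels_factor_analysis(self, rng):
        """Independent oracle: 1-factor ML factor analysis from statsmodels."""
        from statsmodels.multivariate.factor import Factor

        pattern = sp.candidate_patterns()[1]
        pop = sp.build_unitary(0.7)
        for seed in range(5):
            data = sp.generate(pop, 300, seed)
            s = sp.sample_cov(data)
            d = np.diag(1.0 / np.sqrt(np.diag(s)))
            corr = d @ s @ d
            fr = sp.fit_cov(pattern, corr, 300)
            assert fr.converged
            fa = Factor(corr=corr, n_factor=1, method="ml").fit()
            lam = fa.loadings.ravel()
            sigma_sm = np.outer(lam, lam) + np.diag(fa.uniqueness)
            assert fr.F_ml <= sp.fml(corr, sigma_sm) + 1e-6
            ours = np.sort(np.abs(fr.estimates[:13]))
            assert np.allclose(ours, np.sort(np.abs(lam)), atol=1e-4)

    def test_row_permutation_invariance(self, patterns, tripartite_pop, rng):
        data = sp.generate(tripartite_pop, 150, 3)
        perm = rng.permutation(150)
        f1 = sp.fit(patterns[3], data.values)
        f2 = sp.fit(patterns[3], data.values[perm])
        assert f1.converged == f2.converged
        assert f1.F_ml == pytest.approx(f2.F_ml, abs=1e-10)

    def test_marker_and_standardized_reach_same_fit(self, tripartite_pop):
        data = sp.generate(tripartite_pop, 500, 9)
        s = sp.sample_cov(data)
        for build in (lambda: sp.build_unitary(0.5),
                      lambda: sp.build_bipartite(0.5, 0.0),
                      lambda: sp.build_tripartite(0.5, 0.0)):
            std = sp.fit_cov(sp.free_pattern(build(), "variance_standardized"), s, 500)
            mark = sp.fit_cov(sp.free_pattern(build(), "marker"), s, 500)
            assert std.converged and mark.converged
            assert std.F_ml == pytest.approx(mark.F_ml, abs=1e-8)

    def test_statistical_failure_is_flagged_not_raised(self, patterns):
        # 3-factor model on 1-factor data at small n often cannot be fit;
        # the result must come back as data, never as an exception
        pop = sp.build_unitary(0.5)
        results = [
            sp.fit(patterns[3], sp.generate(pop, 50, seed)) for seed in range(8)
        ]
        assert all(isinstance(r.converged, bool) for r in results)

    def test_wishart_multiplier_mode(self, patterns, tripartite_pop):
        data = sp.generate(tripartite_pop, 100, 11)
        s = sp.sample_cov(data)
        f_n = sp.fit_cov(patterns[3], s, 100, multiplier="n")
        f_w = sp.fit_cov(patterns[3], s, 100, multiplier="n-1")
        assert f_w.T == pytest.approx(f_n.T * 99 / 100, rel=1e-9)


class TestBaselineAndSaturated:
    def test_baseline_df_for_thirteen_indicators(self, tripartite_pop):
        data = sp.generate(tripartite_pop, 80, 5)
        base = sp.fit_baseline(data)
        assert base.df == 78  # p(p-1)/2

    def test_diagonal_data_has_zero_baseline_statistic(self):
        base = sp.fit_baseline(np.diag([1.0, 2.0, 0.5]), 50)
        assert base.T == pytest.approx(0.0, abs=1e-12)

    def test_saturated_loglik_bounds_model_loglik(self, patterns, tripartite_pop):
        data = sp.generate(tripartite_pop, 120, 6)
        s = sp.sample_cov(data)
        sat = sp.saturated_loglik(s, 120)
        for mid in (1, 2, 3):
            fr = sp.fit_cov(patterns[mid], s, 120)
            assert fr.converged
            assert sat >= fr.loglik - 1e-9
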