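"""Through-origin regression, goodness of fit, and model ranking."""

import warnings

import numpy as np
import pytest

import saosfit as sf
from saosfit.regression import fit_model


def _sampled(model_name, params, omegas=None, noise=0.0, seed=None, amp=1.0):
    model = sf.get_model(model_name)
    sw = sf.generate_sweep(model, params,
                           omegas if omegas is not None else None,
                           sf.NoiseSpec(noise, seed), strain_amplitude=amp)
    return sf.reconstruct(sw)


class TestFitModel:
    def test_noise_free_burgers_recovers_coefficients(self, burgers,
                                                      toy_burgers_params):
        sam = _sampled("burgers", toy_burgers_params)
        res = fit_model(sam, burgers)
        k_true = sf.forward_coefficients(burgers, toy_burgers_params)
        np.testing.assert_allclose(res.k, k_true, rtol=1e-8)
        assert abs(res.r2 - 1.0) < 1e-12
        assert abs(res.adj_r2 - 1.0) < 1e-12

    def test_response_equal_to_single_column(self, simple_sweep):
        # if sigma happens to equal the eps_dot column exactly, the fit must
        # return K = (1, 0) with zero residuals
        sam = sf.reconstruct(simple_sweep)
        doctored = sf.SampledResponse(
            epsilon=sam.epsilon, epsilon_dot=sam.epsilon_dot,
            epsilon_ddot=sam.epsilon_ddot, sigma=sam.epsilon_dot.copy(),
            sigma_dot=sam.sigma_dot, sigma_ddot=sam.sigma_ddot,
            omega=sam.omega, t=sam.t, n_per_period=sam.n_per_period,
            strain_amplitude=sam.strain_amplitude)
        res = fit_model(doctored, sf.get_model("maxwell"))
        np.testing.assert_allclose(res.k, [1.0, 0.0], atol=1e-12)
        np.testing.assert_allclose(res.residuals, 0.0, atol=1e-12)

    def test_adjusted_r2_arithmetic(self):
        # adj R2 = 1 - (1 - R2) (n-1)/(n-p): R2=0.9, n=100, p=2 -> 0.89898
        r2, n, p = 0.9, 100, 2
        assert 1 - (1 - r2) * (n - 1) / (n - p) == pytest.approx(
            0.8989795918, abs=1e-9)
        # and the fitted values obey it: residual identity + formula check
        sam = _sampled("burgers", {"E1": 697.69, "E2": 511.27,
                                   "eta1": 11.07, "eta2": 8.38},
                       noise=0.05, seed=2)
        res = fit_model(sam, sf.get_model("maxwell"))
        expect = 1 - (1 - res.r2) * (res.n_obs - 1) / (res.n_obs - 2)
        assert res.adj_r2 == pytest.approx(expect, rel=1e-12)
        np.testing.assert_allclose(res.residuals + res.predicted,
                                   res.observed, rtol=1e-12)

    def test_single_frequency_second_derivative_collinearity(self, burgers):
        sw = sf.FrequencySweep(omega=np.array([1.0, 1.001]),
                               g_prime=np.array([1.0, 1.0]),
                               g_double_prime=np.array([2.0, 2.0]))
        with pytest.raises(sf.CollinearDesignError, match="frequencies"):
            fit_model(sf.reconstruct(sw), burgers)

    def test_amplitude_invariance_of_coefficients(self, burgers,
                                                  toy_burgers_params):
        a = fit_model(_sampled("burgers", toy_burgers_params, amp=1.0),
                      burgers)
        b = fit_model(_sampled("burgers", toy_burgers_params, amp=0.03),
                      burgers)
        np.testing.assert_allclose(a.k, b.k, rtol=1e-9)
        assert a.r2 == pytest.approx(b.r2, abs=1e-12)
        assert a.adj_r2 == pytest.approx(b.adj_r2, abs=1e-12)

    def test_matches_statsmodels_reference(self, alginate_params):
        # independent cross-check of coefficients and covariance against a
        # standard OLS implementation (no intercept)
        statsmodels = pytest.importorskip("statsmodels.api")
        sam = _sampled("burgers", alginate_params, noise=0.01, seed=9)
        model = sf.get_model("burgers")
        res = fit_model(sam, model)
        X, y = sf.design_terms(model, sam)
        ref = statsmodels.OLS(y, X).fit()
        np.testing.assert_allclose(res.k, ref.params, rtol=1e-8)
        np.testing.assert_allclose(res.k_covariance, ref.cov_params(),
                                   rtol=1e-6)
        assert res.r2 == pytest.approx(ref.rsquared, rel=1e-10)

    def test_per_frequency_normalization_keeps_exact_fit(self, burgers,
                                                         toy_burgers_params):
        sam = _sampled("burgers", toy_burgers_params)
        res = fit_model(sam, burgers, normalize_per_frequency=True)
        k_true = sf.forward_coefficients(burgers, toy_burgers_params)
        np.testing.assert_allclose(res.k, k_true, rtol=1e-8)
        np.testing.assert_allclose(res.residuals + res.predicted,
                                   res.observed, rtol=1e-10)


class TestNestedMonotonicity:
    def test_superset_terms_never_fit_worse(self, alginate_params):
        # burgers terms contain maxwell's; unadjusted R2 can only grow
        sam = _sampled("burgers", alginate_params, noise=0.02, seed=4)
        r_small = fit_model(sam, sf.get_model("maxwell")).r2
        r_big = fit_model(sam, sf.get_model("burgers")).r2
        assert r_big >= r_small - 1e-12
        # same for kelvin_voigt within zener
        r_kv = fit_model(sam, sf.get_model("kelvin_voigt")).r2
        r_z = fit_model(sam, sf.get_model("zener_k")).r2
        assert r_z >= r_kv - 1e-12


class TestBenchmark:
    def test_kelvin_voigt_chosen_over_zener_by_parsimony(self):
        sam = _sampled("kelvin_voigt", {"E": 32685.11, "eta": 54.18})
        ranking = sf.benchmark_models(sam)
        by_class = {e.model_or_class: e for e in ranking.entries}
        assert by_class["kelvin_voigt"].adj_r2 == pytest.approx(1.0, abs=1e-9)
        assert by_class["zener"].adj_r2 == pytest.approx(1.0, abs=1e-9)
        assert ranking.selected == "kelvin_voigt"

    def test_noisy_burgers_ranks_first_in_most_seeds(self, alginate_params):
        wins = 0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for seed in range(20):
                sam = _sampled("burgers", alginate_params, noise=0.01,
                               seed=seed)
                ranking = sf.benchmark_models(sam)
                wins += ranking.entries[0].model_or_class == "burgers"
        assert wins >= 18

    def test_spring_on_dashpot_data_is_useless(self):
        # over a full period the strain and strain-rate columns are
        # orthogonal, so a spring explains none of a dashpot's stress
        sam = _sampled("dashpot", {"eta": 3.0})
        res = fit_model(sam, sf.get_model("spring"))
        assert abs(res.r2) < 0.05

    def test_one_entry_per_degeneracy_class(self, alginate_params):
        sam = _sampled("burgers", alginate_params)
        ranking = sf.benchmark_models(sam)
        labels = [e.model_or_class for e in ranking.entries]
        assert len(labels) == len(set(labels))
        assert set(labels) == {"spring", "dashpot", "maxwell", "kelvin_voigt",
                               "zener", "lethersich_jeffreys", "burgers"}
        adj = [e.adj_r2 for e in ranking.entries]
        assert adj == sorted(adj, reverse=True)


class TestResiduals:
    def test_noise_free_fit_has_zero_residual_sd(self, burgers,
                                                 toy_burgers_params):
        res = fit_model(_sampled("burgers", toy_burgers_params), burgers)
        summaries = sf.residual_summary([res])
        assert summaries[0]["residual_sd"] < 1e-10

    def test_additive_stress_noise_is_recovered_in_residual_sd(self, burgers,
                                                               toy_burgers_params):
        # Gaussian noise of SD s added directly to the stress response
        # reappears as the residual SD of the true model's fit
        s = 0.5
        sam = _sampled("burgers", toy_burgers_params,
                       omegas=np.logspace(-1, 2, 20))
        rng = np.random.default_rng(123)
        noisy = sf.SampledResponse(
            epsilon=sam.epsilon, epsilon_dot=sam.epsilon_dot,
            epsilon_ddot=sam.epsilon_ddot,
            sigma=sam.sigma + s * rng.standard_normal(sam.n_rows),
            sigma_dot=sam.sigma_dot, sigma_ddot=sam.sigma_ddot,
            omega=sam.omega, t=sam.t, n_per_period=sam.n_per_period,
            strain_amplitude=sam.strain_amplitude)
        res = fit_model(noisy, burgers)
        assert res.residual_sd == pytest.approx(s, rel=0.15)

    def test_lower_residual_sd_means_higher_r2(self, alginate_params):
        sam = _sampled("burgers", alginate_params, noise=0.03, seed=8)
        results = [fit_model(sam, sf.get_model(n))
                   for n in ("maxwell", "kelvin_voigt", "burgers")]
        order_sd = sorted(results, key=lambda r: r.residual_sd)
        order_r2 = sorted(results, key=lambda r: -r.r2)
        assert [r.model_name for r in order_sd] == \
            [r.model_name for r in order_r2]
        summary = sf.residual_summary(results)
        assert [s["model_name"] for s in summary] == \
            [r.model_name for r in order_sd]


class TestObservedVsPredicted:
    def test_perfect_fit_lies_on_identity_line(self, burgers,
                                               toy_burgers_params):
        res = fit_model(_sampled("burgers", toy_burgers_params), burgers)
        measured, calculated, slope = sf.observed_vs_predicted(res)
        np.testing.assert_allclose(calculated, measured, rtol=1e-8)
        assert slope == pytest.approx(1.0, abs=1e-10)

    def test_slope_equals_explained_share(self, alginate_params):
        # through-origin least squares: mean(calc*meas)/mean(meas^2)
        # equals 1 - SSR/sum(meas^2)
        sam = _sampled("burgers", alginate_params, noise=0.05, seed=3)
        res = fit_model(sam, sf.get_model("maxwell"))
        _, _, slope = sf.observed_vs_predicted(res)
        ssr = float(res.residuals @ res.residuals)
        sst = float(res.observed @ res.observed)
        assert slope == pytest.approx(1 - ssr / sst, rel=1e-10)


class TestBootstrap:
    def test_bootstrap_errors_comparable_to_delta_method(self, burgers,
                                                         alginate_params):
        sam = _sampled("burgers", alginate_params, noise=0.01, seed=21)
        res, delta = sf.fit_and_invert(sam, burgers)
        boot = sf.bootstrap_parameters(sam, burgers, n_boot=200, seed=1)
        for s in burgers.param_names:
            assert boot.estimate(s) == pytest.approx(delta.estimate(s))
            # same order of magnitude is all the bootstrap promises
            assert 0.2 < boot.stderr(s) / delta.stderr(s) < 5.0
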