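"""Likelihood, fitting, confidence-interval and AIC tests."""

import dataclasses
import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import binom, norm

from recovery_valley.data_io import ExperimentSchedule, ObservedCounts, RunConfig
from recovery_valley.inference import (LikelihoodContext, binomial_log_pmf,
                                       compare_models, confidence_intervals,
                                       finite_difference_hessian, fit_model,
                                       total_log_likelihood)
from recovery_valley.model import ParameterSet, get_variant, spontaneous_factor
from recovery_valley.success import ActionPolicy, WellGeometry

from oracles import brute_force_loglik

PARAMS = ParameterSet(alpha_p=0.8466, alpha_c=0.9135, beta_p=0.8176,
                      beta_c=0.5038, beta_int=0.4085, sigma_p=0.0158,
                      sigma_c=0.0740, k_sp=0.2175)


class TestBinomialLogPmf:
    def test_values(self):
        assert binomial_log_pmf(10, 10, 1 - 1e-12) == pytest.approx(0.0, abs=1e-10)
        assert binomial_log_pmf(5, 10, 0.5) == pytest.approx(math.log(252 / 1024), rel=1e-10)
        assert binomial_log_pmf(5, 10, 0.5) == pytest.approx(-1.40204, abs=1e-5)
        assert binomial_log_pmf(0, 10, 0.5) == pytest.approx(10 * math.log(0.5), rel=1e-12)

    def test_against_scipy(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            n = int(rng.integers(1, 400))
            s = int(rng.integers(0, n + 1))
            p = float(rng.uniform(0.01, 0.99))
            assert binomial_log_pmf(s, n, p) == pytest.approx(binom.logpmf(s, n, p), rel=1e-10)

    def test_domain(self):
        with pytest.raises(ValueError):
            binomial_log_pmf(11, 10, 0.5)


class TestLikelihoodOracle:
    @pytest.mark.parametrize("nv_action_sum", [True, False])
    @pytest.mark.parametrize("variant", ["mult_log", "add_log", "training_only"])
    def test_three_day_dataset(self, tiny_schedule, tiny_observations, tiny_policy,
                               geometry, variant, nv_action_sum):
        params = PARAMS if get_variant(variant).has_spontaneous else \
            dataclasses.replace(PARAMS, k_sp=None)
        expected = brute_force_loglik(params, variant, tiny_schedule,
                                      tiny_observations, tiny_policy, geometry,
                                      nv_action_sum=nv_action_sum)
        got = total_log_likelihood(params, variant, tiny_schedule, tiny_observations,
                                   tiny_policy, geometry, nv_action_sum=nv_action_sum)
        assert got == pytest.approx(expected, abs=1e-10)

    def test_single_day_reduces_to_binomial_term(self):
        """One no-video day, one well, s=5/10 at p=1/2 gives ln C(10,5)/2^10."""
        sched = ExperimentSchedule(pd.DataFrame({
            "day": [3], "has_training": [False], "well_mm": [np.nan],
            "n_training_trials": [0], "has_test": [True],
            "n_test_trials_per_well": [10],
        }))
        w = 0.013
        # additive-linear model with zero memory: mu = k_sp at day_max exactly
        params = dataclasses.replace(PARAMS, k_sp=1 - w / 2)
        obs = ObservedCounts(
            pd.DataFrame({"day": [3], "well_mm": [13.0], "n": [10], "s": [5]}),
            pd.DataFrame(columns=["day", "well_mm", "action", "n_selected", "s_success"]))
        policy = ActionPolicy(days=(3,), p_precision=(0.5,))
        L_off = total_log_likelihood(params, "add_linear", sched, obs, policy,
                                     nv_action_sum=False)
        assert L_off == pytest.approx(math.log(252 / 1024), rel=1e-10)
        L_on = total_log_likelihood(params, "add_linear", sched, obs, policy,
                                    nv_action_sum=True)
        assert L_on == pytest.approx(2 * L_off, rel=1e-12)


class TestAic:
    def test_identity_and_printed_inversion(self):
        """AIC = 2k - 2L; k=8 with L=-141.455 reproduces the printed 298.91."""
        assert 2 * 8 - 2 * (-141.455) == pytest.approx(298.91)

    def test_parameter_counts(self):
        assert get_variant("training_only").k == 7
        for name in ("mult_log", "add_log", "mult_linear", "add_linear",
                     "mult_exp", "add_exp"):
            assert get_variant(name).k == 8

    def test_fit_result_satisfies_identity(self, tiny_schedule, tiny_observations,
                                           tiny_policy, geometry):
        cfg = RunConfig(n_multistart=2, seed=3)
        res = fit_model("training_only", tiny_schedule, tiny_observations,
                        tiny_policy, geometry, config=cfg, compute_ci=False)
        assert res.aic == 2 * res.k - 2 * res.log_likelihood
        assert res.k == 7


class TestFitModel:
    def test_reproducible_given_seed(self, tiny_schedule, tiny_observations,
                                     tiny_policy, geometry):
        cfg = RunConfig(n_multistart=3, seed=11)
        a = fit_model("mult_log", tiny_schedule, tiny_observations, tiny_policy,
                      geometry, config=cfg, compute_ci=False)
        b = fit_model("mult_log", tiny_schedule, tiny_observations, tiny_policy,
                      geometry, config=cfg, compute_ci=False)
        assert a.theta_hat == b.theta_hat
        assert a.log_likelihood == b.log_likelihood

    def test_estimates_respect_bounds(self, tiny_schedule, tiny_observations,
                                      tiny_policy, geometry):
        cfg = RunConfig(n_multistart=3, seed=5,
                        bounds={"k_sp": (0.0, 0.4), "sigma_p": (0.01, 0.5)})
        res = fit_model("mult_log", tiny_schedule, tiny_observations, tiny_policy,
                        geometry, config=cfg, compute_ci=False)
        assert 0.0 <= res.theta_hat.k_sp <= 0.4
        assert 0.01 <= res.theta_hat.sigma_p <= 0.5

    def test_boundary_estimates_flagged_not_converged(self, tiny_schedule,
                                                      tiny_observations,
                                                      tiny_policy, geometry):
        # squeeze sigma_c into a bound the data cannot satisfy
        cfg = RunConfig(n_multistart=2, seed=5, bounds={"sigma_c": (0.9, 1.0)})
        res = fit_model("mult_log", tiny_schedule, tiny_observations, tiny_policy,
                        geometry, config=cfg, compute_ci=False)
        if "sigma_c" in res.boundary_parameters:
            assert not res.converged


class TestConfidenceIntervals:
    def test_quadratic_log_likelihood(self):
        """For -logL = sum (x_i - a_i)^2 / (2 v_i), half-widths are 2 sqrt(v_i)."""
        a = np.array([1.0, -2.0, 0.3])
        v = np.array([0.5, 0.01, 4.0])

        def nll(x):
            return float(np.sum((x - a) ** 2 / (2 * v)))

        half = confidence_intervals(a, nll)
        assert np.allclose(half, 2 * np.sqrt(v), rtol=1e-6)

    def test_flat_direction_yields_nan_with_warning(self):
        def nll(x):
            return float((x[0] - 1.0) ** 2)  # x[1] is flat

        with pytest.warns(UserWarning):
            half = confidence_intervals(np.array([1.0, 0.0]), nll)
        assert np.isnan(half).any()

    def test_fd_hessian_exact_on_quadratic(self):
        h = np.array([[2.0, 0.5], [0.5, 1.0]])

        def f(x):
            return 0.5 * float(x @ h @ x)

        got = finite_difference_hessian(f, np.array([0.3, -0.2]))
        assert np.allclose(got, h, atol=1e-6)


class TestCompareModels:
    def test_table_bookkeeping(self, tiny_schedule, tiny_observations, tiny_policy,
                               geometry):
        cfg = RunConfig(n_multistart=2, seed=9)
        table, fits = compare_models(tiny_schedule, tiny_observations, tiny_policy,
                                     geometry, cfg)
        assert len(table) == 7
        assert (table["aic"].diff().dropna() >= 0).all()
        assert table["selected"].iloc[0] and not table["selected"].iloc[1:].any()
        assert table["delta_aic"].iloc[0] == 0.0
        ks = dict(zip(table["variant"], table["k"]))
        assert ks["training_only"] == 7
        assert all(v == 8 for n, v in ks.items() if n != "training_only")
        for name, fit in fits.items():
            assert fit.aic == 2 * fit.k - 2 * fit.log_likelihood
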