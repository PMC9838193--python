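"""Unit and property tests for the latent skill-memory dynamics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from recovery_valley.model import (ParameterSet, SkillState, TrialEvent,
                                   VARIANTS, batch_update, get_variant,
                                   performance_map, rest_day_update,
                                   simulate_state_sequence, spontaneous_factor,
                                   trial_update)

MULT_LOG = get_variant("mult_log")
ADD_LOG = get_variant("add_log")


def params(**overrides):
    base = dict(alpha_p=0.8466, alpha_c=0.9135, beta_p=0.8176, beta_c=0.5038,
                beta_int=0.4085, sigma_p=0.0158, sigma_c=0.0740, k_sp=0.2175)
    base.update(overrides)
    return ParameterSet(**base)


class TestSpontaneousFactor:
    @pytest.mark.parametrize("name", [n for n in VARIANTS if n != "training_only"])
    @pytest.mark.parametrize("day_max", [2, 10, 44, 61])
    def test_normalisation_at_day_max(self, name, day_max):
        """The factor equals k_sp at the last modelled day for every variant."""
        k_sp = 0.2175
        assert spontaneous_factor(get_variant(name), k_sp, day_max, day_max) == pytest.approx(k_sp, rel=1e-12)

    def test_log_values(self):
        assert spontaneous_factor(MULT_LOG, 0.2175, 1, 44) == 0.0
        # 0.2175 * ln(10)/ln(44)
        assert spontaneous_factor(MULT_LOG, 0.2175, 10, 44) == pytest.approx(0.2175 * math.log(10) / math.log(44), rel=1e-12)
        assert spontaneous_factor(MULT_LOG, 0.2175, 10, 44) == pytest.approx(0.13234, abs=5e-6)

    @pytest.mark.parametrize("name", [n for n in VARIANTS if n != "training_only"])
    def test_nondecreasing_in_day_and_bounded(self, name):
        variant = get_variant(name)
        vals = [spontaneous_factor(variant, 0.3, d, 50) for d in range(1, 51)]
        assert all(b >= a - 1e-15 for a, b in zip(vals, vals[1:]))
        assert all(0.0 <= v <= 0.3 + 1e-15 for v in vals)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            spontaneous_factor(MULT_LOG, 0.2, 0, 44)
        with pytest.raises(ValueError):
            spontaneous_factor(get_variant("training_only"), 0.2, 3, 44)


class TestPerformanceMap:
    def test_multiplicative_on_zero_memory(self):
        state = SkillState(x_p=0.0, x_c=0.0, day=20)
        out = performance_map(state, params(), MULT_LOG, day_max=44)
        assert out.mu_p == 0.0 and out.mu_c == 0.0

    def test_additive_offset_only(self):
        state = SkillState(x_p=0.0, x_c=0.0, day=61)
        out = performance_map(state, params(k_sp=0.0684), ADD_LOG, day_max=61)
        assert out.mu_p == pytest.approx(0.0684, rel=1e-12)

    def test_multiplicative_scaling(self):
        state = SkillState(x_p=5.0, x_c=0.0, day=10)
        out = performance_map(state, params(), MULT_LOG, day_max=44)
        assert out.mu_p == pytest.approx(5.0 * 0.2175 * math.log(10) / math.log(44), rel=1e-12)
        assert out.mu_p == pytest.approx(0.66172, abs=5e-5)

    def test_training_only_is_identity(self):
        state = SkillState(x_p=1.3, x_c=0.4, day=12)
        out = performance_map(state, params(k_sp=None), get_variant("training_only"), day_max=44)
        assert (out.mu_p, out.mu_c) == (1.3, 0.4)

    @pytest.mark.parametrize("name", ["mult_log", "add_log", "mult_linear", "add_linear"])
    def test_monotone_in_day_for_fixed_nonnegative_memory(self, name):
        variant = get_variant(name)
        p = params()
        mus = [performance_map(SkillState(2.0, 2.0, day=d), p, variant, 44).mu_p
               for d in range(1, 45)]
        assert all(b >= a - 1e-15 for a, b in zip(mus, mus[1:]))


class TestTrialUpdate:
    def test_single_compensatory_trial_from_zero(self):
        state = SkillState(0.0, 0.0)
        nxt = trial_update(state, TrialEvent("compensatory"), params())
        assert nxt.x_p == pytest.approx(0.4085)
        assert nxt.x_c == pytest.approx(0.5038)
        assert nxt.trial_index == 1

    def test_fixed_point_of_constant_use(self):
        """Constant single-skill use converges to beta/(1-alpha)."""
        p = params(beta_int=0.0)
        state = SkillState(0.0, 0.0)
        for _ in range(500):
            state = trial_update(state, TrialEvent("precision"), p)
        assert abs(state.x_p - 0.8176 / (1 - 0.8466)) < 1e-9
        assert state.x_p == pytest.approx(5.32986, abs=5e-6)

    @given(alpha=st.floats(0.0, 1.0), x0=st.floats(-5, 5), k=st.integers(0, 60))
    @settings(max_examples=50, deadline=None)
    def test_decay_closure(self, alpha, x0, k):
        """With no use, k steps give exactly alpha^k * x0."""
        p = params(alpha_p=alpha, alpha_c=alpha)
        x = x0
        for _ in range(k):
            x = p.alpha_p * x  # the no-use limit of the trial update
        assert x == pytest.approx(alpha**k * x0, rel=1e-12, abs=1e-300)
        # and the closed-form batch update agrees with zero input rates
        assert batch_update(x0, alpha, 0.0, 0.0, k, 1.0) == pytest.approx(alpha**k * x0, rel=1e-12, abs=1e-300)

    def test_interaction_decoupling(self):
        """With beta_int = 0, compensatory trials leave x_p unchanged."""
        p = params(beta_int=0.0)
        state = SkillState(1.234, 0.5)
        for _ in range(10):
            state = trial_update(state, TrialEvent("compensatory"), p)
        assert state.x_p == pytest.approx(1.234 * p.alpha_p**10, rel=1e-12)
        assert state.x_c != pytest.approx(0.5 * p.alpha_c**10, rel=1e-3)

    @given(n=st.integers(0, 200), q=st.floats(0, 1), alpha=st.floats(0.1, 0.999))
    @settings(max_examples=40, deadline=None)
    def test_batch_update_matches_iterated_expected_use(self, n, q, alpha):
        """Closed-form n-trial update equals the per-trial recursion."""
        p = params(alpha_p=alpha)
        x = 0.7
        for _ in range(n):
            x = alpha * x + p.beta_p * q + p.beta_int * (1 - q)
        assert batch_update(0.7, alpha, p.beta_p, p.beta_int, n, q) == pytest.approx(x, rel=1e-9, abs=1e-12)


class TestRestDay:
    def test_single_decay(self):
        out = rest_day_update(SkillState(2.0, 1.0, day=9), params())
        assert out.x_p == pytest.approx(2.0 * 0.8466)
        assert out.day == 10

    def test_identity_retention(self):
        out = rest_day_update(SkillState(1.7, 0.3), params(alpha_p=1.0, alpha_c=1.0))
        assert (out.x_p, out.x_c) == (1.7, 0.3)

    def test_two_consecutive_rest_days(self):
        p = params(alpha_p=0.9)
        s = rest_day_update(rest_day_update(SkillState(1.0, 0.0), p), p)
        assert s.x_p == pytest.approx(0.81)


class TestSimulateStateSequence:
    def test_zero_trials_everywhere_stays_zero(self, tiny_policy):
        import pandas as pd

        from recovery_valley.data_io import ExperimentSchedule
        sched = ExperimentSchedule(pd.DataFrame({
            "day": [5, 6, 7], "has_training": [True, True, True],
            "well_mm": [13.0] * 3, "n_training_trials": [0, 0, 0],
            "has_test": [False, False, False], "n_test_trials_per_well": [0, 0, 0],
        }))
        traj = simulate_state_sequence(sched, params(), MULT_LOG, tiny_policy)
        assert (traj[["x_p", "x_c"]].to_numpy() == 0).all()

    def test_linear_accumulation_without_decay(self, tiny_policy):
        import pandas as pd

        from recovery_valley.data_io import ExperimentSchedule
        sched = ExperimentSchedule(pd.DataFrame({
            "day": [5], "has_training": [True], "well_mm": [13.0],
            "n_training_trials": [3], "has_test": [False],
            "n_test_trials_per_well": [0],
        }))
        policy_all_comp = type(tiny_policy)(days=(5,), p_precision=(0.0,))
        p = params(alpha_c=1.0, beta_c=0.1, beta_int=0.0)
        end = batch_update(0.0, p.alpha_c, p.beta_c, p.beta_int, 3, 1.0)
        assert end == pytest.approx(0.3)
        traj = simulate_state_sequence(sched, p, MULT_LOG, policy_all_comp)
        # states are recorded at test-evaluation time (before the day's trials)
        assert traj["x_c"].iloc[0] == 0.0
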