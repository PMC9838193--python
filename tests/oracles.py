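"""Independent oracles used by the test suite.

The brute-force likelihood re-derives every term with scalar scipy.stats
calls and a per-trial state recursion, independently of the vectorised
production path (closed-form geometric sums, ndtr, gammaln).
"""

import numpy as np
from scipy.stats import binom, norm

from recovery_valley.model import get_variant, spontaneous_factor
from recovery_valley.success import policy_at


def brute_force_loglik(params, variant, schedule, observations, policy,
                       geometry, nv_action_sum=True, test_updates=True):
    """Term-by-term likelihood via a per-trial scalar recursion."""
    variant = get_variant(variant) if isinstance(variant, str) else variant
    day_max = schedule.last_day
    x_p = x_c = 0.0
    states = {}
    for _, row in schedule.days.iterrows():
        day = int(row["day"])
        states[day] = (x_p, x_c)
        n_tr = int(row["n_training_trials"]) if row["has_training"] else 0
        n_te = 5 * int(row["n_test_trials_per_well"]) if (row["has_test"] and test_updates) else 0
        if n_tr == 0 and not row["has_test"]:
            x_p *= params.alpha_p
            x_c *= params.alpha_c
            continue
        q = policy_at(policy, day)
        for _ in range(n_te + n_tr):
            x_p = params.alpha_p * x_p + params.beta_p * q + params.beta_int * (1 - q)
            x_c = params.alpha_c * x_c + params.beta_int * q + params.beta_c * (1 - q)

    def mu(day, x):
        if not variant.has_spontaneous:
            return x
        f = spontaneous_factor(variant, params.k_sp, day, day_max)
        return x * f if variant.combine == "multiplicative" else x + f

    def p_success(day, action, well_mm):
        x = states[day][0] if action == "p" else states[day][1]
        sigma = params.sigma_p if action == "p" else params.sigma_c
        thr = 1 - geometry.w0 * well_mm / 2
        p = norm.sf((thr - mu(day, x)) / sigma)
        return min(max(p, 1e-12), 1 - 1e-12)

    total = 0.0
    for _, row in observations.test_counts.iterrows():
        day = int(row["day"])
        q = policy_at(policy, day)
        p = q * p_success(day, "p", row["well_mm"]) + (1 - q) * p_success(day, "c", row["well_mm"])
        p = min(max(p, 1e-12), 1 - 1e-12)
        term = binom.logpmf(row["s"], row["n"], p)
        total += (2 if nv_action_sum else 1) * term
    for _, row in observations.video_counts.iterrows():
        a = "p" if row["action"] == "precision" else "c"
        total += binom.logpmf(row["s_success"], row["n_selected"],
                              p_success(int(row["day"]), a, row["well_mm"]))
    return total
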