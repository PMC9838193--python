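"""Synthetic Kluver-board experiments with the statistical structure the model assumes.

The generator emulates the postlesion protocol: daily training sessions
(5 days/week) whose well size advances from 13 mm toward 10 mm once more than
1,000 pellets have been retrieved from the current size, two daily test sets
of 5 pellets in each of the 5 wells, an exogenous sigmoidal shift of the
action-selection policy from the compensatory toward the precision grip, and
rest-day decay of the skill memories.  Latent dynamics follow the expected
per-trial use under the policy (the same convention the fitter uses), so the
generating trajectory is exactly reproducible from the written dataset; all
observed counts are stochastic binomial draws.

Two ready-made scenarios mirror the two study animals: ``make_monkey_r_fixture``
(multiplicative-log spontaneous recovery, days 8-44) and
``make_monkey_n_fixture`` (additive-log, days 8-61), with generating
parameters equal to the published best-fit estimates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .data_io import (ExperimentSchedule, ObservedCounts, write_observations,
                      write_policy, write_schedule)
from .model import (ModelVariant, ParameterSet, batch_update, get_variant,
                    performance_series)
from .success import (ActionPolicy, WellGeometry, marginal_success_probability,
                      policy_at, success_probability)

__all__ = [
    "MONKEY_R_PARAMS",
    "MONKEY_N_PARAMS",
    "MONKEY_R_VIDEO_DAYS",
    "MONKEY_N_VIDEO_DAYS",
    "SyntheticDataset",
    "generate_policy",
    "generate_schedule",
    "generate_observations",
    "make_monkey_r_fixture",
    "make_monkey_n_fixture",
]

# Published best-fit estimates used as generating truths for the two scenarios.
MONKEY_R_PARAMS = ParameterSet(alpha_p=0.8466, alpha_c=0.9135, beta_p=0.8176,
                               beta_c=0.5038, beta_int=0.4085, sigma_p=0.0158,
                               sigma_c=0.0740, k_sp=0.2175)
MONKEY_N_PARAMS = ParameterSet(alpha_p=0.9961, alpha_c=0.9960, beta_p=0.0035,
                               beta_c=0.0037, beta_int=0.0039, sigma_p=0.0017,
                               sigma_c=0.0184, k_sp=0.0684)

MONKEY_R_VIDEO_DAYS = (12, 16, 21, 24, 31, 33, 34, 35, 38, 44)
MONKEY_N_VIDEO_DAYS = (10, 20, 32, 37, 38, 39, 40, 41, 53, 61)

#: pellets retrieved from one well size before it shrinks the next day
PROGRESSION_THRESHOLD = 1000


@dataclass
class SyntheticDataset:
    """A complete synthetic experiment plus its generating truth."""

    schedule: ExperimentSchedule
    observations: ObservedCounts
    policy: ActionPolicy
    geometry: WellGeometry
    variant: ModelVariant
    truth: ParameterSet
    video_days: tuple[int, ...]
    seed: int
    inflation: int = 1

    @property
    def day_max(self) -> int:
        return self.schedule.last_day

    def write(self, out_dir) -> dict[str, Path]:
        """Write the CSV set plus truth.json; returns the paths written."""
        import json

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "schedule": out / "schedule.csv",
            "test_counts": out / "test_counts.csv",
            "video_counts": out / "video_counts.csv",
            "policy": out / "policy.csv",
            "truth": out / "truth.json",
        }
        write_schedule(self.schedule, paths["schedule"])
        write_observations(self.observations, paths["test_counts"], paths["video_counts"])
        write_policy(self.policy, paths["policy"])
        truth = {
            "variant": self.variant.name,
            "parameters": {k: v for k, v in self.truth.__dict__.items() if v is not None},
            "video_days": list(self.video_days),
            "seed": self.seed,
            "inflation": self.inflation,
            "w0": self.geometry.w0,
        }
        with open(paths["truth"], "w") as fh:
            json.dump(truth, fh, indent=2)
            fh.write("\n")
        return paths


def _logistic(day: float, transition_day: float, steepness: float,
              floor: float, ceiling: float) -> float:
    if math.isinf(steepness):
        return ceiling if day >= transition_day else floor
    z = steepness * (day - transition_day)
    return floor + (ceiling - floor) / (1.0 + math.exp(-z))


def generate_policy(transition_day: float, steepness: float, floor: float,
                    ceiling: float, breakpoint_days: Sequence[int]) -> ActionPolicy:
    """Logistic-in-day compensatory -> precision shift sampled at breakpoints.

    ``p_precision(day) = floor + (ceiling - floor) / (1 + exp(-steepness *
    (day - transition_day)))``, evaluated at the given breakpoint days and
    carried forward piecewise-constant between them.
    """
    if not 0 <= floor <= ceiling <= 1:
        raise ValueError("need 0 <= floor <= ceiling <= 1")
    days = tuple(sorted(int(d) for d in breakpoint_days))
    probs = tuple(_logistic(d, transition_day, steepness, floor, ceiling) for d in days)
    return ActionPolicy(days=days, p_precision=probs)


def _training_day_pattern(first_day: int, last_day: int,
                          video_days: Sequence[int]) -> dict[int, bool]:
    """5-on/2-off weekly pattern anchored at the first training day.

    Days carrying a video-analysed test session are forced to be training/test
    days even when they fall on the weekly rest block (the real calendar
    alignment of the printed test days is unknown).
    """
    video = set(video_days)
    return {day: ((day - first_day) % 7) < 5 or day in video
            for day in range(first_day, last_day + 1)}


def generate_schedule(
    params: ParameterSet,
    variant: ModelVariant | str,
    policy: ActionPolicy,
    geometry: WellGeometry,
    first_day: int = 8,
    last_day: int = 44,
    trials_per_training_day: int = 200,
    seed: int = 0,
    video_days: Sequence[int] = (),
    n_test_trials_per_well: int = 10,
    test_updates: bool = True,
    forced_success_probability: Optional[float] = None,
) -> ExperimentSchedule:
    """Generate the daily schedule, enforcing the 1,000-pellet well progression.

    The well size presented on each training day is determined by the
    simulator's own training successes: when the cumulative number of pellets
    retrieved from the current well size exceeds 1,000, the next smaller size
    is presented from the following training day.  Successes are drawn
    ``Binomial(n_trials, p)`` with ``p`` the policy-marginal success
    probability at the day's latent state (``forced_success_probability``
    overrides ``p`` for protocol tests).  Deterministic for a fixed seed.
    """
    variant = get_variant(variant) if isinstance(variant, str) else variant
    params.validate(variant)
    rng = np.random.default_rng([seed, 0])
    is_training = _training_day_pattern(first_day, last_day, video_days)
    day_max = last_day

    x_p = x_c = 0.0
    well_idx = 0
    cum = 0
    advance_pending = False
    rows = []
    for day in range(first_day, last_day + 1):
        if not is_training[day]:
            rows.append((day, False, np.nan, 0, False, 0))
            x_p *= params.alpha_p
            x_c *= params.alpha_c
            continue
        if advance_pending and well_idx < len(geometry.well_sizes_mm) - 1:
            well_idx += 1
            cum = 0
            advance_pending = False
        well_mm = geometry.well_sizes_mm[well_idx]
        q = policy_at(policy, day)
        # test sets precede the training session within the day
        if test_updates and n_test_trials_per_well > 0:
            n_te = 5 * n_test_trials_per_well
            x_p = batch_update(x_p, params.alpha_p, params.beta_p, params.beta_int, n_te, q)
            x_c = batch_update(x_c, params.alpha_c, params.beta_c, params.beta_int, n_te, 1.0 - q)
        if forced_success_probability is None:
            mu_p = performance_series(np.array([x_p]), np.array([day]),
                                      params.k_sp, variant, day_max)[0]
            mu_c = performance_series(np.array([x_c]), np.array([day]),
                                      params.k_sp, variant, day_max)[0]
            w = geometry.width_of(well_mm)
            p = marginal_success_probability(
                q,
                success_probability(mu_p, params.sigma_p, w),
                success_probability(mu_c, params.sigma_c, w),
            )
        else:
            p = forced_success_probability
        n_tr = trials_per_training_day
        if n_tr:
            cum += int(rng.binomial(n_tr, p))
            x_p = batch_update(x_p, params.alpha_p, params.beta_p, params.beta_int, n_tr, q)
            x_c = batch_update(x_c, params.alpha_c, params.beta_c, params.beta_int, n_tr, 1.0 - q)
        if cum > PROGRESSION_THRESHOLD:
            advance_pending = True
        rows.append((day, True, well_mm, n_tr, True, n_test_trials_per_well))

    df = pd.DataFrame(rows, columns=["day", "has_training", "well_mm",
                                     "n_training_trials", "has_test",
                                     "n_test_trials_per_well"])
    return ExperimentSchedule(df)


def _day_states(schedule: ExperimentSchedule, params: ParameterSet,
                policy: ActionPolicy, test_updates: bool, record: str = "start"):
    from .model import forward_day_states

    df = schedule.days
    days = df["day"].to_numpy()
    n_training = np.where(df["has_training"], df["n_training_trials"], 0)
    n_test = np.where(df["has_test"], 5 * df["n_test_trials_per_well"], 0)
    has_trials = (n_training > 0) | (n_test > 0)
    q = np.array([policy_at(policy, int(d)) if h else 0.0
                  for d, h in zip(days, has_trials)])
    xp, xc = forward_day_states(days, n_training, n_test, q, params,
                                test_updates=test_updates, record=record)
    return days, q, xp, xc


def generate_observations(
    schedule: ExperimentSchedule,
    params: ParameterSet,
    variant: ModelVariant | str,
    geometry: WellGeometry,
    policy: ActionPolicy,
    video_days: Sequence[int] = (),
    seed: int = 0,
    inflation: int = 1,
    test_updates: bool = True,
    forced_success_probability: Optional[float] = None,
) -> ObservedCounts:
    """Draw test-session counts from the forward model.

    On no-video days the per-well success count is
    ``Binomial(n, p_marginal)``; on video days the per-well selections are
    ``Binomial(n, p_precision)`` and the per-action successes are binomial at
    the per-action success probabilities.  ``inflation`` multiplies the number
    of observed test trials per well (replicated measurement) without touching
    the latent dynamics.
    """
    variant = get_variant(variant) if isinstance(variant, str) else variant
    params.validate(variant)
    rng = np.random.default_rng([seed, 1])
    video = set(int(d) for d in video_days)
    day_max = schedule.last_day
    days, q, xp, xc = _day_states(schedule, params, policy, test_updates)
    mu_p = performance_series(xp, days, params.k_sp, variant, day_max)
    mu_c = performance_series(xc, days, params.k_sp, variant, day_max)
    widths = geometry.widths
    wells = geometry.well_sizes_mm

    df = schedule.days
    test_rows, video_rows = [], []
    for i, day in enumerate(days):
        if not df["has_test"].iloc[i]:
            continue
        n = int(df["n_test_trials_per_well"].iloc[i]) * int(inflation)
        if n == 0:
            continue
        p_p = success_probability(mu_p[i], params.sigma_p, widths)
        p_c = success_probability(mu_c[i], params.sigma_c, widths)
        if forced_success_probability is not None:
            p_p = np.full_like(widths, forced_success_probability)
            p_c = np.full_like(widths, forced_success_probability)
        if int(day) in video:
            n_p = rng.binomial(n, q[i], size=len(wells))
            for j, well in enumerate(wells):
                n_c = n - n_p[j]
                video_rows.append((int(day), well, "precision", int(n_p[j]),
                                   int(rng.binomial(n_p[j], p_p[j]))))
                video_rows.append((int(day), well, "compensatory", int(n_c),
                                   int(rng.binomial(n_c, p_c[j]))))
        else:
            p_marg = marginal_success_probability(q[i], p_p, p_c)
            s = rng.binomial(n, p_marg, size=len(wells))
            for j, well in enumerate(wells):
                test_rows.append((int(day), well, n, int(s[j])))

    return ObservedCounts(
        pd.DataFrame(test_rows, columns=["day", "well_mm", "n", "s"]),
        pd.DataFrame(video_rows, columns=["day", "well_mm", "action",
                                          "n_selected", "s_success"]),
    )


def _make_fixture(params: ParameterSet, variant_name: str, video_days: tuple[int, ...],
                  last_day: int, policy_shape: dict, seed: int, inflation: int,
                  trials_per_training_day: int, first_day: int = 8) -> SyntheticDataset:
    geometry = WellGeometry()
    variant = get_variant(variant_name)
    policy = generate_policy(breakpoint_days=(first_day,) + video_days, **policy_shape)
    schedule = generate_schedule(params, variant, policy, geometry,
                                 first_day=first_day, last_day=last_day,
                                 trials_per_training_day=trials_per_training_day,
                                 seed=seed, video_days=video_days)
    observations = generate_observations(schedule, params, variant, geometry,
                                         policy, video_days=video_days,
                                         seed=seed, inflation=inflation)
    return SyntheticDataset(schedule=schedule, observations=observations,
                            policy=policy, geometry=geometry, variant=variant,
                            truth=params, video_days=video_days, seed=seed,
                            inflation=inflation)


def make_monkey_r_fixture(seed: int = 0, inflation: int = 1,
                          trials_per_training_day: int = 200) -> SyntheticDataset:
    """Synthetic 45-day scenario: multiplicative-log spontaneous recovery.

    The policy shifts sigmoidally from nearly-always-compensatory to
    nearly-always-precision around day 30, producing the characteristic
    recovery valley in the marginal success rate.
    """
    return _make_fixture(MONKEY_R_PARAMS, "mult_log", MONKEY_R_VIDEO_DAYS,
                         last_day=44,
                         policy_shape=dict(transition_day=30.0, steepness=0.5,
                                           floor=0.05, ceiling=0.95),
                         seed=seed, inflation=inflation,
                         trials_per_training_day=trials_per_training_day)


def make_monkey_n_fixture(seed: int = 0, inflation: int = 1,
                          trials_per_training_day: int = 200) -> SyntheticDataset:
    """Synthetic 61-day scenario: additive-log spontaneous recovery.

    Retention rates near 1 make memories accumulate across days; the additive
    spontaneous term keeps early success rates above zero.  The policy shift
    is gentler and later than in the 45-day scenario, and both grips are used
    from the start.
    """
    return _make_fixture(MONKEY_N_PARAMS, "add_log", MONKEY_N_VIDEO_DAYS,
                         last_day=61,
                         policy_shape=dict(transition_day=38.0, steepness=0.3,
                                           floor=0.2, ceiling=0.9),
                         seed=seed, inflation=inflation,
                         trials_per_training_day=trials_per_training_day)
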