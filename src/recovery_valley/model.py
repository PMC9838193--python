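"""Latent skill-memory dynamics for two interacting grip skills.

Two state variables track the trained memory of the precision grip (``x_p``)
and the compensatory grip (``x_c``), both zero at the start of postlesional
training.  Each executed trial updates both memories:

    x_p(k+1) = alpha_p * x_p(k) + beta_p * use_p(k) + beta_int * use_c(k)
    x_c(k+1) = alpha_c * x_c(k) + beta_int * use_p(k) + beta_c * use_c(k)

where ``use_a`` indicates which grip was used, ``alpha`` is the per-step
retention (forgetting) rate and ``beta`` the use-dependent update rate;
``beta_int`` is the cross-skill generalisation term.  On days without any
trials the memories decay once: ``x(day+1) = alpha * x(day)``.

The executed skill level ``mu`` equals the memory for the training-only
variant, or the memory combined (multiplicatively or additively) with a
spontaneous-recovery factor ``k_sp * f(day)/f(day_max)`` with
``f in {log, identity, exp}`` for the six spontaneous-recovery variants.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Optional

import numpy as np

__all__ = [
    "ParameterSet",
    "ModelVariant",
    "SkillState",
    "PerformanceLevel",
    "TrialEvent",
    "VARIANTS",
    "VARIANT_NAMES",
    "PARAM_ORDER",
    "get_variant",
    "spontaneous_factor",
    "performance_map",
    "trial_update",
    "rest_day_update",
    "batch_update",
    "simulate_state_sequence",
]

#: canonical parameter ordering used by the optimiser and in serialised output
PARAM_ORDER = (
    "alpha_p",
    "alpha_c",
    "beta_p",
    "beta_c",
    "beta_int",
    "sigma_p",
    "sigma_c",
    "k_sp",
)

#: guard against runaway growth when alpha > 1 in sensitivity simulations
STATE_CAP = 1e12


@dataclass(frozen=True)
class ParameterSet:
    """Free parameters of one model variant.

    alpha_p, alpha_c : per-step retention rates (<= 1 during fitting)
    beta_p, beta_c   : use-dependent update rates, in [0, 1]
    beta_int         : cross-skill interaction update rate, in [0, 1]
    sigma_p, sigma_c : motor-noise SD in normalised motor-command units (> 0)
    k_sp             : spontaneous-recovery gain (>= 0); ``None`` for the
                       training-only variant
    """

    alpha_p: float
    alpha_c: float
    beta_p: float
    beta_c: float
    beta_int: float
    sigma_p: float
    sigma_c: float
    k_sp: Optional[float] = None

    def validate(self, variant: "ModelVariant") -> None:
        vals = [self.alpha_p, self.alpha_c, self.beta_p, self.beta_c,
                self.beta_int, self.sigma_p, self.sigma_c]
        if self.k_sp is not None:
            vals.append(self.k_sp)
        if not all(math.isfinite(v) for v in vals):
            raise ValueError("all parameters must be finite")
        if self.sigma_p <= 0 or self.sigma_c <= 0:
            raise ValueError("motor-noise SDs must be positive")
        if variant.has_spontaneous and self.k_sp is None:
            raise ValueError(f"variant {variant.name!r} requires k_sp")
        if not variant.has_spontaneous and self.k_sp is not None:
            raise ValueError("training_only takes no k_sp")
        if self.k_sp is not None and self.k_sp < 0:
            raise ValueError("k_sp must be non-negative")

    def as_array(self, variant: "ModelVariant") -> np.ndarray:
        names = PARAM_ORDER[: variant.k]
        return np.array([getattr(self, n) for n in names], dtype=float)

    @classmethod
    def from_array(cls, values: Iterable[float], variant: "ModelVariant") -> "ParameterSet":
        values = list(map(float, values))
        if len(values) != variant.k:
            raise ValueError(f"expected {variant.k} values for {variant.name}")
        kwargs = dict(zip(PARAM_ORDER[: variant.k], values))
        return cls(**kwargs)

    def perturb(self, **multipliers: float) -> "ParameterSet":
        """Return a copy with named parameters multiplied by the given factors."""
        changes = {}
        for name, mult in multipliers.items():
            value = getattr(self, name)
            if value is None:
                raise ValueError(f"{name} is absent from this parameter set")
            changes[name] = value * mult
        return replace(self, **changes)


@dataclass(frozen=True)
class ModelVariant:
    """One of the seven candidate models.

    ``combine`` says how the spontaneous-recovery factor enters the
    performance map (``none`` for training-only), ``time_function`` the shape
    of its day dependence.
    """

    name: str
    combine: str  # "none" | "multiplicative" | "additive"
    time_function: str  # "none" | "log" | "linear" | "exp"

    @property
    def has_spontaneous(self) -> bool:
        return self.combine != "none"

    @property
    def k(self) -> int:
        """Number of free parameters: 7 training-only, 8 otherwise."""
        return 8 if self.has_spontaneous else 7


VARIANTS = {
    "training_only": ModelVariant("training_only", "none", "none"),
    "mult_log": ModelVariant("mult_log", "multiplicative", "log"),
    "add_log": ModelVariant("add_log", "additive", "log"),
    "mult_linear": ModelVariant("mult_linear", "multiplicative", "linear"),
    "add_linear": ModelVariant("add_linear", "additive", "linear"),
    "mult_exp": ModelVariant("mult_exp", "multiplicative", "exp"),
    "add_exp": ModelVariant("add_exp", "additive", "exp"),
}
VARIANT_NAMES = tuple(VARIANTS)


def get_variant(name: str) -> ModelVariant:
    try:
        return VARIANTS[name]
    except KeyError:
        raise ValueError(f"unknown model variant {name!r}; choose from {VARIANT_NAMES}") from None


@dataclass(frozen=True)
class SkillState:
    """Latent memories at one point in the trial/day sequence."""

    x_p: float
    x_c: float
    trial_index: int = 0
    day: int = 1


@dataclass(frozen=True)
class PerformanceLevel:
    """Executed skill level of each grip (target = 1)."""

    mu_p: float
    mu_c: float


@dataclass(frozen=True)
class TrialEvent:
    """One executed trial; exactly one grip is used."""

    action: str  # "precision" | "compensatory"

    def __post_init__(self) -> None:
        if self.action not in ("precision", "compensatory"):
            raise ValueError(f"unknown action {self.action!r}")

    @property
    def use_p(self) -> int:
        return 1 if self.action == "precision" else 0

    @property
    def use_c(self) -> int:
        return 1 if self.action == "compensatory" else 0


def spontaneous_factor(variant: ModelVariant, k_sp: float, day: int, day_max: int) -> float:
    """Normalised spontaneous-recovery factor ``k_sp * f(day) / f(day_max)``.

    ``f`` is log, identity or exp of the postlesion day.  The factor is 0 at
    the day where ``f`` vanishes (day 1 for log), nondecreasing in ``day`` and
    exactly ``k_sp`` at ``day_max``.  The exp variant is computed in the
    overflow-safe form ``exp(day - day_max)``.
    """
    if not variant.has_spontaneous:
        raise ValueError("training_only has no spontaneous-recovery factor")
    if k_sp < 0:
        raise ValueError("k_sp must be non-negative")
    if day < 1 or day > day_max:
        raise ValueError(f"day must satisfy 1 <= day <= day_max, got day={day}, day_max={day_max}")
    if variant.time_function == "log":
        if day_max < 2:
            raise ValueError("log time function needs day_max >= 2")
        return k_sp * math.log(day) / math.log(day_max)
    if variant.time_function == "linear":
        return k_sp * day / day_max
    if variant.time_function == "exp":
        return k_sp * math.exp(day - day_max)
    raise AssertionError(f"unreachable time_function {variant.time_function!r}")


def _combine(x: float, factor: float, combine: str) -> float:
    if combine == "multiplicative":
        return x * factor
    if combine == "additive":
        return x + factor
    return x


def performance_map(
    state: SkillState, params: ParameterSet, variant: ModelVariant, day_max: int
) -> PerformanceLevel:
    """Map latent memories to executed skill levels for the given variant."""
    if not variant.has_spontaneous:
        return PerformanceLevel(mu_p=state.x_p, mu_c=state.x_c)
    factor = spontaneous_factor(variant, params.k_sp, state.day, day_max)
    return PerformanceLevel(
        mu_p=_combine(state.x_p, factor, variant.combine),
        mu_c=_combine(state.x_c, factor, variant.combine),
    )


def trial_update(state: SkillState, event: TrialEvent, params: ParameterSet) -> SkillState:
    """Advance the memories by one executed trial."""
    return SkillState(
        x_p=params.alpha_p * state.x_p + params.beta_p * event.use_p + params.beta_int * event.use_c,
        x_c=params.alpha_c * state.x_c + params.beta_int * event.use_p + params.beta_c * event.use_c,
        trial_index=state.trial_index + 1,
        day=state.day,
    )


def rest_day_update(state: SkillState, params: ParameterSet) -> SkillState:
    """One day without trials: memories decay once by their retention rates."""
    return SkillState(
        x_p=params.alpha_p * state.x_p,
        x_c=params.alpha_c * state.x_c,
        trial_index=0,
        day=state.day + 1,
    )


def _geometric_sum(alpha: float, n: int) -> float:
    """1 + alpha + ... + alpha^(n-1), stable for alpha near or above 1."""
    if n == 0:
        return 0.0
    if abs(alpha - 1.0) < 1e-12:
        return float(n)
    return (1.0 - alpha**n) / (1.0 - alpha)


def batch_update(x: float, alpha: float, beta_own: float, beta_cross: float,
                 n: int, q_own: float) -> float:
    """Closed form for ``n`` trials with a constant own-use fraction ``q_own``.

    Each trial contributes the expected increment
    ``c = beta_own * q_own + beta_cross * (1 - q_own)``, so
    ``x' = alpha^n x + c (1 + alpha + ... + alpha^(n-1))``.  Exact when the
    per-trial use indicator is replaced by its expectation under the action
    policy (the estimation convention), and exact for any ordering when
    ``q_own`` is 0 or 1.
    """
    if n < 0:
        raise ValueError("trial count must be non-negative")
    c = beta_own * q_own + beta_cross * (1.0 - q_own)
    an = alpha**n if n else 1.0
    out = an * x + c * _geometric_sum(alpha, n)
    return max(-STATE_CAP, min(STATE_CAP, out))


def forward_day_states(
    days: np.ndarray,
    n_training: np.ndarray,
    n_test: np.ndarray,
    q: np.ndarray,
    params: ParameterSet,
    test_updates: bool = True,
    record: str = "start",
) -> tuple[np.ndarray, np.ndarray]:
    """Latent memories for each day of a schedule.

    With ``record="start"`` (the evaluation convention for test sessions) the
    recorded state is the one carried over from the previous day — the state
    the day's test sets see, before that day's own trials — and one success
    probability per day/well is held across the day's test trials.  With
    ``record="end"`` the state after the day's trials (or rest decay) is
    recorded instead; this is the smooth profile used for sensitivity
    trajectories.  Days with no trials at all decay the memories once.
    Arrays must cover every day in the modelled span.

    Returns ``(x_p, x_c)`` aligned with ``days``.
    """
    if record not in ("start", "end"):
        raise ValueError("record must be 'start' or 'end'")
    m = len(days)
    x_p = 0.0
    x_c = 0.0
    xp_rec = np.empty(m)
    xc_rec = np.empty(m)
    ap, ac = params.alpha_p, params.alpha_c
    bp, bc, bi = params.beta_p, params.beta_c, params.beta_int
    for i in range(m):
        if record == "start":
            xp_rec[i] = x_p
            xc_rec[i] = x_c
        n_tr = int(n_training[i])
        n_te = int(n_test[i]) if test_updates else 0
        if n_tr == 0 and int(n_test[i]) == 0:
            x_p *= ap
            x_c *= ac
        else:
            qi = float(q[i])
            # test trials precede the training session within the day
            if n_te:
                x_p = batch_update(x_p, ap, bp, bi, n_te, qi)
                x_c = batch_update(x_c, ac, bc, bi, n_te, 1.0 - qi)
            if n_tr:
                x_p = batch_update(x_p, ap, bp, bi, n_tr, qi)
                x_c = batch_update(x_c, ac, bc, bi, n_tr, 1.0 - qi)
        if record == "end":
            xp_rec[i] = x_p
            xc_rec[i] = x_c
    return xp_rec, xc_rec


def performance_series(
    x: np.ndarray, days: np.ndarray, k_sp: Optional[float],
    variant: ModelVariant, day_max: int,
) -> np.ndarray:
    """Vectorised performance map over a per-day memory series."""
    if not variant.has_spontaneous:
        return np.asarray(x, dtype=float)
    d = np.asarray(days, dtype=float)
    if variant.time_function == "log":
        if day_max < 2:
            raise ValueError("log time function needs day_max >= 2")
        g = np.log(d) / math.log(day_max)
    elif variant.time_function == "linear":
        g = d / day_max
    else:
        g = np.exp(d - float(day_max))
    factor = k_sp * g
    if variant.combine == "multiplicative":
        return np.asarray(x, float) * factor
    return np.asarray(x, float) + factor


def simulate_state_sequence(schedule, params: ParameterSet, variant: ModelVariant,
                            policy, day_max: Optional[int] = None,
                            test_updates: bool = True):
    """Deterministic per-day trajectory of memories and skill levels.

    ``schedule`` is a :class:`recovery_valley.data_io.ExperimentSchedule` and
    ``policy`` an :class:`recovery_valley.success.ActionPolicy`; per-trial use
    indicators are replaced by their expectation under the policy.  Returns a
    DataFrame with one row per day: the memories at test-evaluation time and
    the corresponding skill levels ``mu_p``, ``mu_c``.
    """
    import pandas as pd

    from .success import policy_at

    params.validate(variant)
    df = schedule.days
    days = df["day"].to_numpy()
    if day_max is None:
        day_max = int(days.max())
    n_training = np.where(df["has_training"].to_numpy(), df["n_training_trials"].to_numpy(), 0)
    n_test = np.where(df["has_test"].to_numpy(), 5 * df["n_test_trials_per_well"].to_numpy(), 0)
    needs_policy = (n_training > 0) | (n_test > 0)
    q = np.array([policy_at(policy, int(d)) if need else 0.0
                  for d, need in zip(days, needs_policy)])
    xp, xc = forward_day_states(days, n_training, n_test, q, params, test_updates=test_updates)
    mu_p = performance_series(xp, days, params.k_sp, variant, day_max)
    mu_c = performance_series(xc, days, params.k_sp, variant, day_max)
    return pd.DataFrame({
        "day": days, "x_p": xp, "x_c": xc, "mu_p": mu_p, "mu_c": mu_c,
        "p_precision": q, "has_test": df["has_test"].to_numpy(),
    })
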