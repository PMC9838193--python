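"""Binomial maximum-likelihood fitting, confidence intervals and AIC comparison.

The likelihood forward-simulates the latent memories over the actual schedule,
maps them to per-day, per-well success probabilities and scores the observed
counts with binomial terms: marginalised over the action policy on days
without video records, per action on video days.  Following the printed
likelihood, the no-video terms are summed over both actions (a factor 2, since
they do not depend on the action); ``nv_action_sum=False`` removes the factor.

Estimation is bounded local optimisation (L-BFGS-B) from seeded random
multistarts; 95% confidence half-widths are ``2 * sqrt(diag(H^-1))`` with
``H`` the central finite-difference Hessian of the negative log-likelihood at
the maximum; model comparison uses ``AIC = 2k - 2L``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import gammaln, ndtr

from .data_io import ExperimentSchedule, ObservedCounts, RunConfig, validate
from .model import (PARAM_ORDER, STATE_CAP, ModelVariant, ParameterSet,
                    forward_day_states, get_variant, performance_series)
from .success import ActionPolicy, WellGeometry, clip_probability, policy_at

__all__ = [
    "DEFAULT_BOUNDS",
    "FitResult",
    "binomial_log_pmf",
    "LikelihoodContext",
    "total_log_likelihood",
    "fit_model",
    "confidence_intervals",
    "compare_models",
]

#: fitting bounds per parameter (the published constraints are alpha <= 1 and
#: 0 <= beta <= 1; sigma and k_sp bounds are pragmatic box constraints)
DEFAULT_BOUNDS = {
    "alpha_p": (0.0, 1.0),
    "alpha_c": (0.0, 1.0),
    "beta_p": (0.0, 1.0),
    "beta_c": (0.0, 1.0),
    "beta_int": (0.0, 1.0),
    "sigma_p": (1e-4, 1.0),
    "sigma_c": (1e-4, 1.0),
    "k_sp": (0.0, 10.0),
}


def binomial_log_pmf(s, n, p):
    """log Binomial(s | n, p) via log-gamma; ``p`` is clamped away from 0/1."""
    s = np.asarray(s, dtype=float)
    n = np.asarray(n, dtype=float)
    if np.any(s < 0) or np.any(s > n):
        raise ValueError("need 0 <= s <= n")
    p = clip_probability(np.asarray(p, dtype=float))
    log_c = gammaln(n + 1) - gammaln(s + 1) - gammaln(n - s + 1)
    out = log_c + s * np.log(p) + (n - s) * np.log1p(-p)
    return float(out) if out.ndim == 0 else out


@dataclass
class FitResult:
    """Maximum-likelihood fit of one model variant."""

    variant: str
    theta_hat: ParameterSet
    ci: dict[str, float]
    log_likelihood: float
    aic: float
    k: int
    converged: bool
    best_start: int
    n_evals: int
    seed: int
    boundary_parameters: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {
            "variant": self.variant,
            "theta_hat": {k: v for k, v in self.theta_hat.__dict__.items() if v is not None},
            # NaN half-widths (flat or boundary directions) serialise as null
            "ci": {k: (v if np.isfinite(v) else None) for k, v in self.ci.items()},
            "log_likelihood": self.log_likelihood,
            "aic": self.aic,
            "k": self.k,
            "converged": self.converged,
            "best_start": self.best_start,
            "n_evals": self.n_evals,
            "seed": self.seed,
            "boundary_parameters": list(self.boundary_parameters),
        }


class LikelihoodContext:
    """Precompiled arrays for fast repeated log-likelihood evaluation."""

    def __init__(
        self,
        variant: ModelVariant | str,
        schedule: ExperimentSchedule,
        observations: ObservedCounts,
        policy: ActionPolicy,
        geometry: Optional[WellGeometry] = None,
        nv_action_sum: bool = True,
        test_trials_update: bool = True,
        reward_region: str = "one_sided",
        day_max: Optional[int] = None,
        check: bool = True,
    ) -> None:
        self.variant = get_variant(variant) if isinstance(variant, str) else variant
        self.geometry = geometry or WellGeometry()
        if check:
            validate(schedule, observations, policy, self.geometry).raise_if_failed()
        if reward_region != "one_sided":
            raise NotImplementedError("likelihood currently uses the one-sided reward region")

        df = schedule.days
        self.days = df["day"].to_numpy()
        self.day_max = int(day_max if day_max is not None else self.days.max())
        self.n_training = np.where(df["has_training"], df["n_training_trials"], 0)
        n_test = np.where(df["has_test"], 5 * df["n_test_trials_per_well"], 0)
        self.n_test = n_test
        self.test_trials_update = bool(test_trials_update)
        has_trials = (self.n_training > 0) | (n_test > 0)
        self.q_day = np.array([policy_at(policy, int(d)) if h else 0.0
                               for d, h in zip(self.days, has_trials)])
        pos = {int(d): i for i, d in enumerate(self.days)}

        tc = observations.test_counts
        self._nv_idx = tc["day"].map(pos).to_numpy(dtype=int)
        self._nv_thr = 1.0 - self.geometry.w0 * tc["well_mm"].to_numpy() / 2.0
        self._nv_s = tc["s"].to_numpy(dtype=float)
        self._nv_n = tc["n"].to_numpy(dtype=float)
        self._nv_logc = (gammaln(self._nv_n + 1) - gammaln(self._nv_s + 1)
                         - gammaln(self._nv_n - self._nv_s + 1))
        self._nv_q = self.q_day[self._nv_idx]
        self.nv_weight = 2.0 if nv_action_sum else 1.0

        vc = observations.video_counts
        by_action = {}
        for action in ("precision", "compensatory"):
            sub = vc[vc["action"] == action]
            idx = sub["day"].map(pos).to_numpy(dtype=int)
            thr = 1.0 - self.geometry.w0 * sub["well_mm"].to_numpy() / 2.0
            s = sub["s_success"].to_numpy(dtype=float)
            n = sub["n_selected"].to_numpy(dtype=float)
            logc = gammaln(n + 1) - gammaln(s + 1) - gammaln(n - s + 1)
            by_action[action] = (idx, thr, s, n, logc)
        self._video = by_action
        self.n_evals = 0

    def _mu(self, params: ParameterSet) -> tuple[np.ndarray, np.ndarray]:
        xp, xc = forward_day_states(self.days, self.n_training, self.n_test,
                                    self.q_day, params,
                                    test_updates=self.test_trials_update)
        if np.any(np.abs(xp) >= STATE_CAP) or np.any(np.abs(xc) >= STATE_CAP):
            raise FloatingPointError(
                "latent state overflow (runaway retention rate alpha > 1?): "
                f"alpha_p={params.alpha_p}, alpha_c={params.alpha_c}")
        mu_p = performance_series(xp, self.days, params.k_sp, self.variant, self.day_max)
        mu_c = performance_series(xc, self.days, params.k_sp, self.variant, self.day_max)
        return mu_p, mu_c

    def loglik(self, params: ParameterSet) -> float:
        """Total log-likelihood L(theta) over no-video and video terms."""
        self.n_evals += 1
        mu_p, mu_c = self._mu(params)
        total = 0.0
        if len(self._nv_idx):
            p_p = ndtr((mu_p[self._nv_idx] - self._nv_thr) / params.sigma_p)
            p_c = ndtr((mu_c[self._nv_idx] - self._nv_thr) / params.sigma_c)
            p = clip_probability(self._nv_q * p_p + (1.0 - self._nv_q) * p_c)
            terms = self._nv_logc + self._nv_s * np.log(p) + \
                (self._nv_n - self._nv_s) * np.log1p(-p)
            total += self.nv_weight * float(terms.sum())
        for action, sigma, mu in (("precision", params.sigma_p, mu_p),
                                  ("compensatory", params.sigma_c, mu_c)):
            idx, thr, s, n, logc = self._video[action]
            if len(idx) == 0:
                continue
            p = clip_probability(ndtr((mu[idx] - thr) / sigma))
            terms = logc + s * np.log(p) + (n - s) * np.log1p(-p)
            total += float(terms.sum())
        if not np.isfinite(total):
            raise FloatingPointError(f"non-finite log-likelihood at {params}")
        return total

    def loglik_vector(self, theta: np.ndarray) -> float:
        return self.loglik(ParameterSet.from_array(theta, self.variant))

    def negloglik_vector(self, theta: np.ndarray) -> float:
        return -self.loglik_vector(theta)

    def penalised_negloglik(self, theta: np.ndarray) -> float:
        """Optimizer objective: overflow/invalid regions map to a huge value."""
        try:
            return -self.loglik_vector(theta)
        except (FloatingPointError, ValueError):
            return 1e12


def total_log_likelihood(
    params: ParameterSet,
    variant: ModelVariant | str,
    schedule: ExperimentSchedule,
    observations: ObservedCounts,
    policy: ActionPolicy,
    geometry: Optional[WellGeometry] = None,
    nv_action_sum: bool = True,
    test_trials_update: bool = True,
    day_max: Optional[int] = None,
) -> float:
    """L(theta): forward-simulate the schedule and sum binomial log terms."""
    ctx = LikelihoodContext(variant, schedule, observations, policy, geometry,
                            nv_action_sum=nv_action_sum,
                            test_trials_update=test_trials_update,
                            day_max=day_max)
    return ctx.loglik(params)


def _bounds_arrays(variant: ModelVariant,
                   bounds: Optional[dict] = None) -> tuple[np.ndarray, np.ndarray]:
    merged = dict(DEFAULT_BOUNDS)
    if bounds:
        merged.update({k: tuple(v) for k, v in bounds.items()})
    names = PARAM_ORDER[: variant.k]
    lo = np.array([merged[n][0] for n in names])
    hi = np.array([merged[n][1] for n in names])
    return lo, hi


def fit_model(
    variant: ModelVariant | str,
    schedule: ExperimentSchedule,
    observations: ObservedCounts,
    policy: ActionPolicy,
    geometry: Optional[WellGeometry] = None,
    config: Optional[RunConfig] = None,
    compute_ci: bool = True,
) -> FitResult:
    """Bounded ML estimation with seeded uniform multistarts.

    Runs ``config.n_multistart`` L-BFGS-B searches from starts drawn uniformly
    within the bounds, keeps the best, and polishes it with a Nelder-Mead pass
    followed by a final L-BFGS-B refinement.  Reproducible given
    ``config.seed``.
    """
    config = config or RunConfig()
    variant = get_variant(variant) if isinstance(variant, str) else variant
    ctx = LikelihoodContext(variant, schedule, observations, policy, geometry,
                            nv_action_sum=config.nv_action_sum,
                            test_trials_update=config.test_trials_update,
                            reward_region=config.reward_region)
    lo, hi = _bounds_arrays(variant, config.bounds)
    rng = np.random.default_rng(config.seed)
    starts = lo + (hi - lo) * rng.uniform(size=(max(1, config.n_multistart), variant.k))

    best = None
    best_idx = -1
    any_converged = False
    bounds_list = list(zip(lo, hi))
    for i, x0 in enumerate(starts):
        res = minimize(ctx.penalised_negloglik, x0, method="L-BFGS-B",
                       bounds=bounds_list,
                       options={"ftol": config.tol, "gtol": 1e-10, "maxiter": 500})
        if res.fun >= 1e11:
            continue
        any_converged = any_converged or res.success
        if best is None or res.fun < best.fun:
            best, best_idx = res, i
    if best is None:
        raise RuntimeError("all multistarts failed to evaluate the likelihood")

    # polish: simplex escape from any flat/kinked region, then refine
    polish = minimize(ctx.penalised_negloglik, best.x, method="Nelder-Mead",
                      bounds=bounds_list,
                      options={"xatol": 1e-9, "fatol": config.tol, "maxiter": 4000})
    x_best = np.clip(polish.x, lo, hi)
    refine = minimize(ctx.penalised_negloglik, x_best, method="L-BFGS-B",
                      bounds=bounds_list,
                      options={"ftol": config.tol, "gtol": 1e-12, "maxiter": 1000})
    if refine.fun <= polish.fun:
        x_hat, final_nll = np.asarray(refine.x), float(refine.fun)
    else:
        x_hat, final_nll = x_best, float(polish.fun)

    theta_hat = ParameterSet.from_array(x_hat, variant)
    log_l = -final_nll
    names = PARAM_ORDER[: variant.k]
    tol_b = 1e-6 * np.maximum(1.0, np.abs(hi))
    at_bound = tuple(n for n, x, l, h, t in zip(names, x_hat, lo, hi, tol_b)
                     if x - l < t or h - x < t)
    ci = {n: float("nan") for n in names}
    if compute_ci:
        half = confidence_intervals(x_hat, ctx.negloglik_vector, lo, hi)
        ci = {n: float(h) for n, h in zip(names, half)}
    return FitResult(
        variant=variant.name,
        theta_hat=theta_hat,
        ci=ci,
        log_likelihood=log_l,
        aic=2.0 * variant.k - 2.0 * log_l,
        k=variant.k,
        converged=bool(any_converged and not at_bound),
        best_start=best_idx,
        n_evals=ctx.n_evals,
        seed=config.seed,
        boundary_parameters=at_bound,
    )


def finite_difference_hessian(f, x: np.ndarray, rel_step: float = 1e-4) -> np.ndarray:
    """Central finite-difference Hessian with step ``rel_step*max(1, |x_i|)``."""
    x = np.asarray(x, dtype=float)
    k = len(x)
    h = rel_step * np.maximum(1.0, np.abs(x))
    hess = np.empty((k, k))
    f0 = f(x)
    for i in range(k):
        ei = np.zeros(k)
        ei[i] = h[i]
        hess[i, i] = (f(x + ei) - 2.0 * f0 + f(x - ei)) / h[i] ** 2
        for j in range(i + 1, k):
            ej = np.zeros(k)
            ej[j] = h[j]
            hess[i, j] = hess[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4.0 * h[i] * h[j])
    return hess


def confidence_intervals(theta_hat: np.ndarray, negloglik, lo=None, hi=None,
                         rel_step: float = 1e-4) -> np.ndarray:
    """95% half-widths ``2*sqrt(diag(H^-1))`` from the observed information.

    ``H`` is the central finite-difference Hessian of the *negative*
    log-likelihood at the maximum.  Flat or negative-curvature directions
    yield NaN half-widths with a warning rather than a silent number;
    parameters at a bound are flagged the same way by the caller.
    """
    theta_hat = np.asarray(theta_hat, dtype=float)
    hess = finite_difference_hessian(negloglik, theta_hat, rel_step=rel_step)
    half = np.full(len(theta_hat), np.nan)
    try:
        cov = np.linalg.inv(hess)
    except np.linalg.LinAlgError:
        warnings.warn("Hessian is singular; confidence intervals are undefined (NaN)")
        return half
    diag = np.diag(cov)
    bad = ~(diag > 0)
    if bad.any():
        warnings.warn(
            "non-positive curvature for parameters at indices "
            f"{np.flatnonzero(bad).tolist()}; their confidence intervals are NaN")
    half[~bad] = 2.0 * np.sqrt(diag[~bad])
    return half


def compare_models(
    schedule: ExperimentSchedule,
    observations: ObservedCounts,
    policy: ActionPolicy,
    geometry: Optional[WellGeometry] = None,
    config: Optional[RunConfig] = None,
    variants: Sequence[str] = ("training_only", "mult_log", "add_log",
                              "mult_linear", "add_linear", "mult_exp", "add_exp"),
    compute_ci: bool = False,
) -> tuple[pd.DataFrame, dict[str, FitResult]]:
    """Fit every candidate variant and rank them by AIC (ascending).

    Returns the ranked table (winner first, flagged in the ``selected``
    column) and the per-variant :class:`FitResult` objects.
    """
    config = config or RunConfig()
    fits: dict[str, FitResult] = {}
    for name in variants:
        import dataclasses as _dc
        fits[name] = fit_model(name, schedule, observations, policy, geometry,
                               config=_dc.replace(config, variant=name),
                               compute_ci=compute_ci)
    table = pd.DataFrame(
        [{"variant": n, "k": r.k, "log_likelihood": r.log_likelihood,
          "aic": r.aic, "converged": r.converged} for n, r in fits.items()]
    ).sort_values("aic", kind="stable").reset_index(drop=True)
    table["selected"] = [i == 0 for i in range(len(table))]
    table["delta_aic"] = table["aic"] - table["aic"].iloc[0]
    return table, fits
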