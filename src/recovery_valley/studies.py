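"""Simulation studies: parameter recovery and model-selection recovery.

Both studies generate replicate synthetic experiments whose generating truths
are the published best-fit parameter sets, refit them, and summarise how well
estimation recovers the truth.  They are the package's substitute for
re-analysing the original animals, whose data are not deposited.
"""

from __future__ import annotations

from typing import Callable, Optional

import numpy as np

from .data_io import RunConfig
from .inference import compare_models, fit_model
from .synth import make_monkey_n_fixture, make_monkey_r_fixture

__all__ = ["parameter_recovery_study", "model_selection_study", "FIXTURES"]

FIXTURES: dict[str, Callable] = {"R": make_monkey_r_fixture, "N": make_monkey_n_fixture}


def _replicate_seeds(base_seed: int, n: int) -> list[tuple[int, int]]:
    """(data_seed, fit_seed) pairs for replicates 1..n, derived from one seed."""
    return [(1000 * base_seed + i, 2000 * base_seed + i) for i in range(1, n + 1)]


def parameter_recovery_study(
    monkey: str = "R",
    n_replicates: int = 10,
    inflation: int = 20,
    n_multistart: int = 20,
    base_seed: int = 1,
    progress: Optional[Callable[[str], None]] = None,
) -> dict:
    """Generate-and-refit study against the published generating truth.

    Each replicate simulates a full experiment at the scenario's truth
    (test counts inflated ``inflation``-fold), refits the generating variant
    by bounded ML with ``n_multistart`` starts, and records the estimates.
    Returns the per-replicate estimates, their medians and the median's
    relative error per parameter.
    """
    fixture = FIXTURES[monkey]
    replicates = []
    truth = None
    for data_seed, fit_seed in _replicate_seeds(base_seed, n_replicates):
        ds = fixture(seed=data_seed, inflation=inflation)
        truth = ds.truth
        cfg = RunConfig(variant=ds.variant.name, n_multistart=n_multistart,
                        seed=fit_seed, inflation=inflation)
        res = fit_model(ds.variant, ds.schedule, ds.observations, ds.policy,
                        ds.geometry, config=cfg, compute_ci=False)
        est = {k: v for k, v in res.theta_hat.__dict__.items() if v is not None}
        est["log_likelihood"] = res.log_likelihood
        replicates.append(est)
        if progress:
            progress(f"replicate seed={data_seed}: L={res.log_likelihood:.2f}")
    names = [k for k in replicates[0] if k != "log_likelihood"]
    medians = {k: float(np.median([r[k] for r in replicates])) for k in names}
    rel_err = {k: abs(medians[k] - getattr(truth, k)) / abs(getattr(truth, k))
               for k in names}
    return {
        "monkey": monkey,
        "variant": "mult_log" if monkey == "R" else "add_log",
        "n_replicates": n_replicates,
        "inflation": inflation,
        "n_multistart": n_multistart,
        "truth": {k: getattr(truth, k) for k in names},
        "median_estimates": medians,
        "median_relative_error": rel_err,
        "replicates": replicates,
    }


def model_selection_study(
    monkey: str = "R",
    n_replicates: int = 10,
    inflation: int = 20,
    n_multistart: int = 8,
    base_seed: int = 1,
    progress: Optional[Callable[[str], None]] = None,
) -> dict:
    """How often AIC ranks the generating variant first across replicates."""
    fixture = FIXTURES[monkey]
    winners = []
    truth_variant = None
    for data_seed, fit_seed in _replicate_seeds(base_seed, n_replicates):
        ds = fixture(seed=data_seed, inflation=inflation)
        truth_variant = ds.variant.name
        cfg = RunConfig(n_multistart=n_multistart, seed=fit_seed)
        table, _ = compare_models(ds.schedule, ds.observations, ds.policy,
                                  ds.geometry, cfg)
        winners.append(str(table["variant"].iloc[0]))
        if progress:
            progress(f"replicate seed={data_seed}: winner={winners[-1]}")
    wins = sum(w == truth_variant for w in winners)
    return {
        "monkey": monkey,
        "generating_variant": truth_variant,
        "winners": winners,
        "n_replicates": n_replicates,
        "win_fraction": wins / n_replicates,
    }
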