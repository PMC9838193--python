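"""Parameter-perturbation sensitivity analysis and pipeline orchestration.

Sensitivity runs re-simulate the noiseless marginal success-rate trajectory
(the expected success probability itself, averaged without weights over the
five wells) after multiplying one parameter — or the retention-rate pair —
by a set of factors.  The recovery valley is quantified as the largest drop
of the trajectory from a preceding running maximum (``valley_metrics``).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import platform
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .data_io import (ExperimentSchedule, ObservedCounts, RunConfig,
                      read_observations, read_policy, read_schedule, validate,
                      write_fit_result)
from .model import ModelVariant, ParameterSet, get_variant, performance_series
from .success import ActionPolicy, WellGeometry, marginal_success_probability, success_probability
from .synth import SyntheticDataset, _day_states

__all__ = [
    "SENSITIVITY_TARGETS",
    "DEFAULT_MULTIPLIERS",
    "success_rate_trajectory",
    "run_sensitivity",
    "valley_metrics",
    "run_pipeline",
]

#: parameters (or pairs) the analysis perturbs, and their customary factors
SENSITIVITY_TARGETS = ("beta_p", "beta_c", "beta_int", "alpha_pair", "k_sp")
DEFAULT_MULTIPLIERS = {
    "beta_p": (2.0, 1.0, 0.0),
    "beta_c": (2.0, 1.0, 0.0),
    "beta_int": (2.0, 1.0, 0.0),
    "alpha_pair": (1.02, 1.0, 0.98),
    "k_sp": (1.1, 1.0, 0.9),
}


def success_rate_trajectory(
    params: ParameterSet,
    variant: ModelVariant | str,
    schedule: ExperimentSchedule,
    policy: ActionPolicy,
    geometry: Optional[WellGeometry] = None,
    test_updates: bool = True,
    record: str = "end",
) -> pd.DataFrame:
    """Noiseless per-test-day marginal success rate, averaged over the wells.

    Deterministic: no binomial draws, just the model's expected success
    probability per day.  By default the state *after* each day's sessions is
    used (``record="end"``), giving the smooth recovery profile free of
    post-rest-day dips; ``record="start"`` evaluates at the state the test
    sessions actually see.
    """
    variant = get_variant(variant) if isinstance(variant, str) else variant
    params.validate(variant)
    geometry = geometry or WellGeometry()
    days, q, xp, xc = _day_states(schedule, params, policy, test_updates, record=record)
    day_max = schedule.last_day
    mu_p = performance_series(xp, days, params.k_sp, variant, day_max)
    mu_c = performance_series(xc, days, params.k_sp, variant, day_max)
    widths = geometry.widths
    has_test = schedule.days["has_test"].to_numpy()
    rows = []
    for i, day in enumerate(days):
        if not has_test[i]:
            continue
        p_p = success_probability(mu_p[i], params.sigma_p, widths)
        p_c = success_probability(mu_c[i], params.sigma_c, widths)
        p = marginal_success_probability(q[i], p_p, p_c)
        rows.append((int(day), float(np.mean(p))))
    return pd.DataFrame(rows, columns=["day", "success_rate"])


def _perturbed(params: ParameterSet, target: str, mult: float) -> ParameterSet:
    if target == "alpha_pair":
        return params.perturb(alpha_p=mult, alpha_c=mult)
    if target not in SENSITIVITY_TARGETS:
        raise ValueError(f"unknown sensitivity target {target!r}; "
                         f"choose from {SENSITIVITY_TARGETS}")
    out = params.perturb(**{target: mult})
    if out.sigma_p <= 0 or out.sigma_c <= 0:
        raise ValueError("perturbation made a motor-noise SD non-positive")
    return out


def run_sensitivity(
    base_theta: ParameterSet,
    variant: ModelVariant | str,
    schedule: ExperimentSchedule,
    policy: ActionPolicy,
    geometry: Optional[WellGeometry] = None,
    target: str = "beta_int",
    multipliers: Optional[Sequence[float]] = None,
) -> dict[float, pd.DataFrame]:
    """Success-rate trajectories under multiplicative perturbations of one target.

    ``alpha_pair`` scales both retention rates jointly (values above 1 are
    allowed here, unlike during fitting).  Multiplier 1 reproduces the
    unperturbed trajectory exactly.
    """
    if target not in SENSITIVITY_TARGETS:
        raise ValueError(f"unknown sensitivity target {target!r}; "
                         f"choose from {SENSITIVITY_TARGETS}")
    if multipliers is None:
        multipliers = DEFAULT_MULTIPLIERS[target]
    out: dict[float, pd.DataFrame] = {}
    for mult in multipliers:
        params = _perturbed(base_theta, target, float(mult))
        out[float(mult)] = success_rate_trajectory(params, variant, schedule,
                                                   policy, geometry)
    return out


def valley_metrics(trajectory) -> tuple[float, Optional[int]]:
    """Largest fractional peak-to-trough drop of a success-rate series.

    Depth is ``max_t (M_t - v_t) / M_t`` where ``M_t`` is the running maximum
    up to ``t`` — the relative loss of success rate from the best level seen
    so far.  A fractional measure keeps the metric comparable across
    perturbations that suppress the whole curve: a collapse to zero is a
    full-depth (1.0) valley regardless of how high the preceding peak was.

    ``trajectory`` is a DataFrame with ``day``/``success_rate`` columns or a
    plain sequence of rates.  Returns ``(depth, day_of_trough)``; depth is 0
    (day ``None``) iff the series is nondecreasing.
    """
    if isinstance(trajectory, pd.DataFrame):
        values = trajectory["success_rate"].to_numpy(dtype=float)
        days = trajectory["day"].to_numpy()
    else:
        values = np.asarray(trajectory, dtype=float)
        days = np.arange(1, len(values) + 1)
    if len(values) < 3:
        raise ValueError("trajectory needs at least 3 points")
    running_max = np.maximum.accumulate(values)
    with np.errstate(invalid="ignore", divide="ignore"):
        drops = np.where(running_max > 0, (running_max - values) / running_max, 0.0)
    depth = float(drops.max())
    if depth <= 0.0:
        return 0.0, None
    return depth, int(days[int(drops.argmax())])


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(
    config: RunConfig,
    out_dir,
    dataset: Optional[SyntheticDataset] = None,
    data_dir=None,
    sensitivity_targets: Sequence[str] = SENSITIVITY_TARGETS,
    make_plots: bool = True,
) -> dict:
    """simulate/load -> validate -> compare -> sensitivity -> report bundle.

    Provide either a :class:`SyntheticDataset` or a ``data_dir`` containing
    the CSV set.  Writes the dataset (when simulating), a FitResult JSON per
    variant, the AIC table, sensitivity trajectories, plots and a manifest
    with seeds and content hashes.  Rerunning with the same config and seed
    reproduces all numeric outputs byte for byte.
    """
    from .inference import compare_models

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    if dataset is not None:
        schedule, observations, policy = dataset.schedule, dataset.observations, dataset.policy
        geometry = dataset.geometry
        written.update(dataset.write(out / "data"))
    elif data_dir is not None:
        data_dir = Path(data_dir)
        for name in ("schedule.csv", "test_counts.csv", "policy.csv"):
            if not (data_dir / name).exists():
                raise FileNotFoundError(f"missing input file: {data_dir / name}")
        schedule = read_schedule(data_dir / "schedule.csv")
        observations = read_observations(data_dir / "test_counts.csv",
                                         data_dir / "video_counts.csv")
        policy = read_policy(data_dir / "policy.csv")
        geometry = WellGeometry(w0=config.w0)
    else:
        raise ValueError("run_pipeline needs a dataset or a data_dir")

    validate(schedule, observations, policy, geometry).raise_if_failed()

    table, fits = compare_models(schedule, observations, policy, geometry, config)
    aic_path = out / "aic_table.csv"
    table.to_csv(aic_path, index=False)
    written["aic_table"] = aic_path
    for name, fit in fits.items():
        path = out / f"fit_{name}.json"
        write_fit_result(fit, path)
        written[f"fit_{name}"] = path

    winner = table["variant"].iloc[0]
    best = fits[winner]
    sens_frames = []
    if best.theta_hat.k_sp is None:
        sensitivity_targets = tuple(t for t in sensitivity_targets if t != "k_sp")
    for target in sensitivity_targets:
        for mult, traj in run_sensitivity(best.theta_hat, winner, schedule,
                                          policy, geometry, target=target).items():
            depth, valley_day = valley_metrics(traj)
            traj = traj.assign(target=target, multiplier=mult,
                               valley_depth=depth, valley_day=valley_day)
            sens_frames.append(traj)
    sens = pd.concat(sens_frames, ignore_index=True)
    sens_path = out / "sensitivity.csv"
    sens.to_csv(sens_path, index=False)
    written["sensitivity"] = sens_path

    if make_plots:
        written.update(_plot_report(out, best, schedule, policy, geometry, sens))

    manifest = {
        "config": config.to_dict(),
        "seed": config.seed,
        "python": platform.python_version(),
        "selected_variant": winner,
        "n_fit_results": len(fits),
        "fit_results": [fits[n].to_dict() for n in fits],
        "files": {k: {"path": str(p), "sha256": _sha256(Path(p))}
                  for k, p in written.items() if Path(p).suffix != ".png"},
    }
    manifest_path = out / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
        fh.write("\n")
    manifest["manifest_path"] = str(manifest_path)
    return manifest


def _plot_report(out: Path, best, schedule, policy, geometry, sens: pd.DataFrame) -> dict:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    written = {}
    traj = success_rate_trajectory(best.theta_hat, best.variant, schedule, policy, geometry)
    fig, ax = plt.subplots(figsize=(6, 3.5))
    ax.plot(traj["day"], traj["success_rate"], marker="o", ms=3)
    ax.set(xlabel="postlesion day", ylabel="marginal success rate",
           title=f"predicted recovery profile ({best.variant})", ylim=(-0.02, 1.02))
    fig.tight_layout()
    path = out / "recovery_profile.png"
    fig.savefig(path, dpi=120)
    plt.close(fig)
    written["recovery_profile_plot"] = path

    targets = sens["target"].unique()
    fig, axes = plt.subplots(len(targets), 1, figsize=(6, 2.2 * len(targets)),
                             sharex=True, squeeze=False)
    for ax, target in zip(axes.ravel(), targets):
        sub = sens[sens["target"] == target]
        for mult, grp in sub.groupby("multiplier"):
            ax.plot(grp["day"], grp["success_rate"], label=f"x{mult:g}")
        ax.set_ylabel(target)
        ax.set_ylim(-0.02, 1.02)
        ax.legend(fontsize=7, loc="upper left")
    axes.ravel()[-1].set_xlabel("postlesion day")
    fig.tight_layout()
    path = out / "sensitivity.png"
    fig.savefig(path, dpi=120)
    plt.close(fig)
    written["sensitivity_plot"] = path
    return written
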