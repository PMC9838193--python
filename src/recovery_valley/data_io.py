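"""Plain-text I/O for schedules, observed counts, action policies and run configs.

All tabular artefacts are UTF-8 CSV with header rows:

``schedule.csv``      day, has_training, well_mm, n_training_trials, has_test, n_test_trials_per_well
``test_counts.csv``   day, well_mm, n, s                      (days without video)
``video_counts.csv``  day, well_mm, action, n_selected, s_success
``policy.csv``        day, p_precision
``config.json``       run configuration

Schedules are normalised so that every day in the modelled span has an
explicit record; days without training or tests are rest days.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .success import ActionPolicy, WellGeometry

__all__ = [
    "ExperimentSchedule",
    "ObservedCounts",
    "RunConfig",
    "ValidationReport",
    "read_schedule",
    "write_schedule",
    "read_observations",
    "write_observations",
    "read_policy",
    "write_policy",
    "read_config",
    "write_config",
    "write_fit_result",
    "read_fit_result",
    "validate",
]

SCHEDULE_COLUMNS = ["day", "has_training", "well_mm", "n_training_trials",
                    "has_test", "n_test_trials_per_well"]
TEST_COLUMNS = ["day", "well_mm", "n", "s"]
VIDEO_COLUMNS = ["day", "well_mm", "action", "n_selected", "s_success"]


@dataclass
class ExperimentSchedule:
    """Ordered per-day records of training and test sessions.

    ``days`` has one row per postlesion day in the modelled span with columns
    ``SCHEDULE_COLUMNS``.  ``well_mm`` is NaN on days without training.
    """

    days: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.days.copy()
        missing = set(SCHEDULE_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"schedule is missing columns: {sorted(missing)}")
        df = df[SCHEDULE_COLUMNS].sort_values("day").reset_index(drop=True)
        df["day"] = df["day"].astype(int)
        if df["day"].duplicated().any():
            dup = df.loc[df["day"].duplicated(), "day"].tolist()
            raise ValueError(f"duplicate schedule days: {dup}")
        for col in ("has_training", "has_test"):
            df[col] = df[col].astype(bool)
        for col in ("n_training_trials", "n_test_trials_per_well"):
            df[col] = df[col].fillna(0).astype(int)
            if (df[col] < 0).any():
                raise ValueError(f"negative counts in column {col}")
        # normalise: absent days inside the span become explicit rest days
        span = np.arange(df["day"].iloc[0], df["day"].iloc[-1] + 1)
        if len(span) != len(df):
            full = pd.DataFrame({"day": span})
            df = full.merge(df, on="day", how="left")
            for col in ("has_training", "has_test"):
                df[col] = df[col].notna() & df[col].eq(True)
            for col in ("n_training_trials", "n_test_trials_per_well"):
                df[col] = df[col].fillna(0).astype(int)
        self.days = df

    @property
    def first_day(self) -> int:
        return int(self.days["day"].iloc[0])

    @property
    def last_day(self) -> int:
        return int(self.days["day"].iloc[-1])

    @property
    def training_days(self) -> np.ndarray:
        return self.days.loc[self.days["has_training"], "day"].to_numpy()

    @property
    def test_days(self) -> np.ndarray:
        return self.days.loc[self.days["has_test"], "day"].to_numpy()


@dataclass
class ObservedCounts:
    """Per-day, per-well success counts; per-action on video days.

    ``test_counts`` holds the no-video records (s successes out of n marginal
    test trials); ``video_counts`` holds per-action selection and success
    counts for video days.  A given (day, well) appears in exactly one of the
    two tables.
    """

    test_counts: pd.DataFrame
    video_counts: pd.DataFrame

    def __post_init__(self) -> None:
        tc = self.test_counts.copy()
        vc = self.video_counts.copy()
        if tc.empty:
            tc = pd.DataFrame(columns=TEST_COLUMNS)
        if vc.empty:
            vc = pd.DataFrame(columns=VIDEO_COLUMNS)
        for df, cols, name in ((tc, TEST_COLUMNS, "test_counts"),
                               (vc, VIDEO_COLUMNS, "video_counts")):
            missing = set(cols) - set(df.columns)
            if missing:
                raise ValueError(f"{name} is missing columns: {sorted(missing)}")
        tc = tc[TEST_COLUMNS].astype({"day": int, "well_mm": float, "n": int, "s": int})
        vc = vc[VIDEO_COLUMNS].astype({"day": int, "well_mm": float, "action": str,
                                       "n_selected": int, "s_success": int})
        self.test_counts = tc.sort_values(["day", "well_mm"], ascending=[True, False]).reset_index(drop=True)
        self.video_counts = vc.sort_values(["day", "well_mm", "action"],
                                           ascending=[True, False, True]).reset_index(drop=True)

    @property
    def video_days(self) -> np.ndarray:
        return np.unique(self.video_counts["day"].to_numpy())


@dataclass
class RunConfig:
    """Run configuration for simulation and fitting."""

    variant: str = "mult_log"
    w0: float = 0.001
    reward_region: str = "one_sided"  # or "two_sided"
    bounds: Optional[dict[str, tuple[float, float]]] = None
    n_multistart: int = 20
    tol: float = 1e-8
    seed: int = 0
    nv_action_sum: bool = True
    test_trials_update: bool = True
    inflation: int = 1

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if d["bounds"] is not None:
            d["bounds"] = {k: list(v) for k, v in d["bounds"].items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        if d.get("bounds"):
            d["bounds"] = {k: tuple(v) for k, v in d["bounds"].items()}
        return cls(**d)


@dataclass
class ValidationReport:
    """Collected dataset problems; empty means the dataset is usable."""

    errors: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors

    def raise_if_failed(self) -> None:
        if self.errors:
            raise ValueError("dataset validation failed:\n" + "\n".join(self.errors))


def _read_csv(path, columns, name):
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - message formatting only
        raise ValueError(f"could not parse {name} file {path}: {exc}") from exc
    missing = set(columns) - set(df.columns)
    if missing:
        raise ValueError(f"{name} file {path} is missing columns {sorted(missing)}")
    bad = df[columns].isna().any(axis=1)
    # well_mm may be blank on rest days of a schedule; other files allow no blanks
    if name != "schedule" and bad.any():
        rows = (df.index[bad] + 2).tolist()  # +2: header + 1-based
        raise ValueError(f"{name} file {path} has malformed rows (lines {rows})")
    return df


def read_schedule(path) -> ExperimentSchedule:
    df = _read_csv(path, SCHEDULE_COLUMNS, "schedule")
    return ExperimentSchedule(df)


def write_schedule(schedule: ExperimentSchedule, path) -> None:
    schedule.days.to_csv(path, index=False)


def read_observations(test_path, video_path=None) -> ObservedCounts:
    tc = _read_csv(test_path, TEST_COLUMNS, "test_counts")
    if video_path is not None and Path(video_path).exists():
        vc = _read_csv(video_path, VIDEO_COLUMNS, "video_counts")
    else:
        vc = pd.DataFrame(columns=VIDEO_COLUMNS)
    return ObservedCounts(tc, vc)


def write_observations(obs: ObservedCounts, test_path, video_path) -> None:
    obs.test_counts.to_csv(test_path, index=False)
    obs.video_counts.to_csv(video_path, index=False)


def read_policy(path) -> ActionPolicy:
    df = _read_csv(path, ["day", "p_precision"], "policy")
    return ActionPolicy(days=tuple(df["day"].astype(int)),
                        p_precision=tuple(df["p_precision"].astype(float)))


def write_policy(policy: ActionPolicy, path) -> None:
    pd.DataFrame({"day": policy.days, "p_precision": policy.p_precision}).to_csv(path, index=False)


def read_config(path) -> RunConfig:
    with open(path) as fh:
        return RunConfig.from_dict(json.load(fh))


def write_config(config: RunConfig, path) -> None:
    with open(path, "w") as fh:
        json.dump(config.to_dict(), fh, indent=2)
        fh.write("\n")


def write_fit_result(result, path) -> None:
    """Serialise a :class:`recovery_valley.inference.FitResult` as JSON."""
    with open(path, "w") as fh:
        json.dump(result.to_dict(), fh, indent=2)
        fh.write("\n")


def read_fit_result(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def validate(schedule: ExperimentSchedule, observations: ObservedCounts,
             policy: ActionPolicy,
             geometry: Optional[WellGeometry] = None) -> ValidationReport:
    """Cross-check a dataset against the protocol invariants.

    Checks: observation days exist in the schedule and are test days; well
    sizes come from the board geometry; success counts do not exceed trial
    counts; per-well video selections sum to the per-well test-trial count;
    no (day, well) appears both with and without video; the policy covers
    every day with trials.
    """
    report = ValidationReport()
    geometry = geometry or WellGeometry()
    sched = schedule.days.set_index("day")
    known_wells = set(geometry.well_sizes_mm)

    def check_day(day: int, src: str) -> None:
        if day not in sched.index:
            report.errors.append(f"{src}: day {day} is not in the schedule span")
        elif not sched.loc[day, "has_test"]:
            report.errors.append(f"{src}: day {day} is not a test day in the schedule")

    tc, vc = observations.test_counts, observations.video_counts
    for day in np.unique(tc["day"]):
        check_day(int(day), "test_counts")
    for day in np.unique(vc["day"]):
        check_day(int(day), "video_counts")

    for name, df in (("test_counts", tc), ("video_counts", vc)):
        bad_wells = sorted(set(df["well_mm"]) - known_wells)
        if bad_wells:
            report.errors.append(f"{name}: unknown well sizes {bad_wells}")

    over = tc[tc["s"] > tc["n"]]
    for _, row in over.iterrows():
        report.errors.append(
            f"test_counts: day {row.day} well {row.well_mm}: s={row.s} exceeds n={row.n}")
    over_v = vc[vc["s_success"] > vc["n_selected"]]
    for _, row in over_v.iterrows():
        report.errors.append(
            f"video_counts: day {row.day} well {row.well_mm} action {row.action}: "
            f"s={row.s_success} exceeds n={row.n_selected}")

    dup = tc.duplicated(subset=["day", "well_mm"])
    for _, row in tc[dup].iterrows():
        report.errors.append(f"test_counts: duplicate (day {row.day}, well {row.well_mm})")
    dup_v = vc.duplicated(subset=["day", "well_mm", "action"])
    for _, row in vc[dup_v].iterrows():
        report.errors.append(
            f"video_counts: duplicate (day {row.day}, well {row.well_mm}, {row.action})")

    # video-day selections must sum to the per-well number of test trials
    if not vc.empty:
        sums = vc.groupby(["day", "well_mm"])["n_selected"].sum()
        for (day, well), total in sums.items():
            if day in sched.index:
                expected = int(sched.loc[day, "n_test_trials_per_well"])
                # inflated observation counts are multiples of the nominal count
                if expected > 0 and total % expected != 0 and total != expected:
                    report.errors.append(
                        f"video_counts: day {day} well {well}: selections sum to {total}, "
                        f"not a whole number of {expected}-trial test sets")

    both = set(map(tuple, tc[["day", "well_mm"]].to_numpy())) & set(
        map(tuple, vc[["day", "well_mm"]].to_numpy()))
    for day, well in sorted(both):
        report.errors.append(
            f"(day {int(day)}, well {well}) appears in both test_counts and video_counts")

    trial_days = sched.index[(sched["has_training"]) | (sched["has_test"])]
    if len(trial_days) and policy.days[0] > int(trial_days.min()):
        report.errors.append(
            f"policy starts at day {policy.days[0]} but trials begin on day {int(trial_days.min())}")
    return report
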