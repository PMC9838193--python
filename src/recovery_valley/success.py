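"""Observation model: from executed skill level to pellet-retrieval success probability.

A grip attempt is modelled as a noisy motor command ``u ~ N(mu, sigma^2)`` on a
normalised command axis where 1 is the ideal command.  Retrieval from a well of
normalised width ``w`` succeeds when the command exceeds the near edge of the
reward region, ``1 - w/2`` (overshoot always succeeds in the default, one-sided
reward region; a two-sided variant that also requires ``u < 1 + w/2`` is
available via ``reward_region="two_sided"``).  The physical well diameters are
mapped to normalised widths by a fixed task-demand scale ``w0``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import ndtr

__all__ = [
    "PROB_FLOOR",
    "WellGeometry",
    "ActionPolicy",
    "clip_probability",
    "success_probability",
    "marginal_success_probability",
    "policy_at",
]

#: probabilities are clamped to [PROB_FLOOR, 1 - PROB_FLOOR] before any log
PROB_FLOOR = 1e-12

DEFAULT_WELL_SIZES_MM = (13.0, 12.0, 11.0, 10.5, 10.0)


@dataclass(frozen=True)
class WellGeometry:
    """Kluver-board well diameters and the mm -> normalised-width scale.

    ``w0`` converts a well diameter in mm into the width of the reward region
    on the normalised motor-command axis: ``w = w0 * size_mm``.  It is a fixed
    configuration constant, not a fitted parameter.
    """

    well_sizes_mm: tuple[float, ...] = DEFAULT_WELL_SIZES_MM
    w0: float = 0.001
    target_center: float = 1.0

    def __post_init__(self) -> None:
        sizes = tuple(float(s) for s in self.well_sizes_mm)
        object.__setattr__(self, "well_sizes_mm", sizes)
        if any(b >= a for a, b in zip(sizes, sizes[1:], strict=False)):
            raise ValueError("well sizes must be strictly decreasing")
        if not self.w0 > 0:
            raise ValueError("w0 must be positive")
        if any(not 0 < self.w0 * s < 1 for s in sizes):
            raise ValueError("normalised widths w0*size must lie in (0, 1)")

    @property
    def widths(self) -> np.ndarray:
        """Normalised reward-window widths, one per well."""
        return self.w0 * np.asarray(self.well_sizes_mm, dtype=float)

    def width_of(self, size_mm: float) -> float:
        return self.w0 * float(size_mm)


@dataclass(frozen=True)
class ActionPolicy:
    """Piecewise-constant probability of selecting the precision grip.

    Breakpoints are (day, p_precision) pairs measured on video days; the value
    is carried forward until the next breakpoint.  The compensatory-grip
    probability is ``1 - p_precision``.
    """

    days: tuple[int, ...]
    p_precision: tuple[float, ...]

    def __post_init__(self) -> None:
        days = tuple(int(d) for d in self.days)
        probs = tuple(float(p) for p in self.p_precision)
        object.__setattr__(self, "days", days)
        object.__setattr__(self, "p_precision", probs)
        if len(days) != len(probs) or not days:
            raise ValueError("policy needs matching, non-empty days and probabilities")
        if any(b <= a for a, b in zip(days, days[1:], strict=False)):
            raise ValueError("policy breakpoint days must be strictly increasing")
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("p_precision must lie in [0, 1]")

    def at(self, day: int) -> float:
        return policy_at(self, day)


def clip_probability(p):
    """Clamp probabilities away from exact 0/1 before they enter a log."""
    return np.clip(p, PROB_FLOOR, 1.0 - PROB_FLOOR)


def success_probability(mu, sigma, w, reward_region: str = "one_sided"):
    """P(success) for a command ``u ~ N(mu, sigma^2)`` and reward width ``w``.

    One-sided (default): success iff ``u > 1 - w/2``, i.e.
    ``1 - Phi((1 - w/2 - mu)/sigma)``.  Two-sided additionally requires
    ``u < 1 + w/2``.  Strictly increasing in ``mu`` and in ``w`` (one-sided).
    Accepts scalars or broadcastable arrays; probabilities are clamped to
    ``[1e-12, 1 - 1e-12]``.
    """
    mu = np.asarray(mu, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    w = np.asarray(w, dtype=float)
    if np.any(sigma <= 0):
        raise ValueError("sigma must be positive")
    if np.any((w <= 0) | (w >= 1)):
        raise ValueError("normalised well width must lie in (0, 1)")
    lower = 1.0 - w / 2.0
    p = ndtr((mu - lower) / sigma)
    if reward_region == "two_sided":
        p = p - ndtr((mu - (1.0 + w / 2.0)) / sigma)
    elif reward_region != "one_sided":
        raise ValueError(f"unknown reward_region: {reward_region!r}")
    out = clip_probability(p)
    return float(out) if out.ndim == 0 else out


def marginal_success_probability(p_precision, p_succ_p, p_succ_c):
    """Success probability marginalised over the action-selection policy.

    ``p = p(precision)*p_succ_p + p(compensatory)*p_succ_c`` — a convex
    combination lying between the two per-action probabilities.
    """
    q = np.asarray(p_precision, dtype=float)
    if np.any((q < 0) | (q > 1)):
        raise ValueError("p_precision must lie in [0, 1]")
    return q * np.asarray(p_succ_p, float) + (1.0 - q) * np.asarray(p_succ_c, float)


def policy_at(policy: ActionPolicy, day: int) -> float:
    """Policy value at ``day``: most recent breakpoint at or before ``day``."""
    idx = int(np.searchsorted(policy.days, day, side="right")) - 1
    if idx < 0:
        raise ValueError(
            f"day {day} precedes the first policy breakpoint (day {policy.days[0]}); "
            "no carry-backward without an explicit breakpoint"
        )
    return policy.p_precision[idx]
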