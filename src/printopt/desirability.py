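"""Derringer-type desirability construction and formulation optimization.

Each release goal ("not more than 30 % at 2 h", "at least 80 % at 8 h", ...)
maps the predicted response to a per-goal desirability d in [0, 1] through a
one-sided linear ramp of configurable width; the overall objective is the
importance-weighted geometric mean

    D = (prod d_i ^ r_i) ^ (1 / sum r_i),

which is zero as soon as any goal is fully violated and one only when every
goal is fully met.  The optimizer maximizes D over the bounded mixture
simplex using a trained surrogate network: a coarse deterministic grid scan
picks multi-start points which are then refined with Nelder-Mead in the
2 degrees of freedom of the simplex slice.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.optimize import minimize

from .data import DesignBounds, Formulation
from .synthetic import check_feasible, exposure_time_rule, sample_simplex
from .ann import TrainedMLP, predict_release

__all__ = [
    "GoalSpec",
    "DesirabilityResult",
    "EXTENDED_RELEASE_GOALS",
    "goal_desirability",
    "overall_desirability",
    "optimize_formulation",
]


@dataclass(frozen=True)
class GoalSpec:
    """One release target at one dissolution time point."""

    time: float  # h
    direction: str  # "at_most" | "at_least"
    limit: float  # % released
    importance: int = 1  # relative weight (count of "pluses")
    ramp_width: float = 20.0  # % over which d falls linearly from 1 to 0

    def __post_init__(self) -> None:
        if self.direction not in ("at_most", "at_least"):
            raise ValueError("direction must be 'at_most' or 'at_least'")
        if not (0.0 < self.limit < 100.0):
            raise ValueError("limit must lie in (0, 100) %")
        if self.importance < 1:
            raise ValueError("importance must be a positive integer")
        if self.ramp_width <= 0:
            raise ValueError("ramp_width must be positive")


#: Extended-release targets: at most 30/60/70 % released at 2/4/6 h and at
#: least 80 % at 8 h, the later goals weighted more heavily (3 vs 2).
EXTENDED_RELEASE_GOALS = (
    GoalSpec(time=2.0, direction="at_most", limit=30.0, importance=2),
    GoalSpec(time=4.0, direction="at_most", limit=60.0, importance=2),
    GoalSpec(time=6.0, direction="at_most", limit=70.0, importance=3),
    GoalSpec(time=8.0, direction="at_least", limit=80.0, importance=3),
)


@dataclass(frozen=True)
class DesirabilityResult:
    composition: Formulation
    per_goal_d: tuple[float, ...]
    overall_D: float
    predicted_profile: tuple[float, ...]
    profile_times: tuple[float, ...]
    feasible: bool = True

    def __post_init__(self) -> None:
        if not (0.0 <= self.overall_D <= 1.0):
            raise ValueError("overall desirability must lie in [0, 1]")


def goal_desirability(value: float, goal: GoalSpec, hard: bool = False) -> float:
    """Per-goal desirability of one predicted response value.

    ``hard=True`` replaces the linear ramp with a 0/1 threshold.
    """
    if goal.direction == "at_most":
        excess = value - goal.limit
    else:
        excess = goal.limit - value
    if excess <= 0:
        return 1.0
    if hard:
        return 0.0
    return float(max(0.0, 1.0 - excess / goal.ramp_width))


def overall_desirability(
    d: Sequence[float], importances: Sequence[float]
) -> float:
    """Importance-weighted geometric mean of per-goal desirabilities."""
    d = np.asarray(d, dtype=float)
    r = np.asarray(importances, dtype=float)
    if d.shape != r.shape:
        raise ValueError("one importance per desirability is required")
    if np.any((d < 0) | (d > 1)):
        raise ValueError("desirabilities must lie in [0, 1]")
    if np.any(d == 0.0):
        return 0.0
    return float(np.exp(np.sum(r * np.log(d)) / np.sum(r)))


def _profile_indices(times: Sequence[float], goals: Sequence[GoalSpec]) -> list[int]:
    idx = []
    for g in goals:
        matches = [i for i, t in enumerate(times) if abs(t - g.time) < 1e-9]
        if not matches:
            raise ValueError(
                f"surrogate time grid {tuple(times)} has no point at {g.time} h"
            )
        idx.append(matches[0])
    return idx


def _evaluate(
    surrogate: TrainedMLP,
    components: np.ndarray,
    goals: Sequence[GoalSpec],
    goal_idx: list[int],
    hard: bool,
) -> tuple[float, tuple[float, ...], np.ndarray]:
    f = Formulation(
        id="candidate",
        pegda=float(components[0]),
        peg400=float(components[1]),
        water=float(components[2]),
    )
    exposure = (
        exposure_time_rule(f.water) if surrogate.n_inputs == 4 else None
    )
    profile = predict_release(surrogate, f, exposure_time=exposure)
    d = tuple(
        goal_desirability(float(profile[i]), g, hard=hard)
        for i, g in zip(goal_idx, goals)
    )
    D = overall_desirability(d, [g.importance for g in goals])
    return D, d, profile


def optimize_formulation(
    surrogate: TrainedMLP,
    bounds: DesignBounds = DesignBounds(),
    goals: Sequence[GoalSpec] = EXTENDED_RELEASE_GOALS,
    n_starts: int = 8,
    seed: int = 0,
    grid_step: float = 2.0,
    hard: bool = False,
) -> DesirabilityResult:
    """Maximize overall desirability over the bounded mixture simplex.

    A deterministic grid at ``grid_step`` % resolution (plus seeded random
    fill) is scanned first; the ``n_starts`` best grid points seed local
    Nelder-Mead refinements in (pegda, peg400) with water taken as the
    simplex remainder and out-of-bounds moves penalized.  When every
    candidate has D = 0 the result is flagged infeasible and carries the
    best-found profile.
    """
    check_feasible(bounds)
    if not surrogate.times:
        raise ValueError("surrogate has no associated dissolution time grid")
    goal_idx = _profile_indices(surrogate.times, goals)
    lo, hi = bounds.lowers, bounds.uppers
    total = bounds.mixture_total

    # deterministic coarse grid over the simplex slice
    pegda_grid = np.arange(lo[0], hi[0] + 1e-9, grid_step)
    peg_grid = np.arange(lo[1], hi[1] + 1e-9, grid_step)
    cand = []
    for a in pegda_grid:
        for b in peg_grid:
            w = total - a - b
            if lo[2] - 1e-9 <= w <= hi[2] + 1e-9:
                cand.append((a, b, np.clip(w, lo[2], hi[2])))
    rng = np.random.default_rng(seed)
    if len(cand) < n_starts:
        cand.extend(map(tuple, sample_simplex(bounds, n_starts, rng)))
    cand = np.array(cand)

    scored = []
    for c in cand:
        D, d, profile = _evaluate(surrogate, c, goals, goal_idx, hard)
        scored.append((D, tuple(c)))
    scored.sort(key=lambda s: (-s[0], s[1]))
    starts = [np.array(c) for _, c in scored[:n_starts]]

    def negative_D(free: np.ndarray) -> float:
        a, b = free
        w = total - a - b
        x = np.array([a, b, w])
        if np.any(x < lo - 1e-9) or np.any(x > hi + 1e-9):
            # linear pull back toward the box keeps Nelder-Mead informed
            overshoot = float(
                np.sum(np.maximum(lo - x, 0) + np.maximum(x - hi, 0))
            )
            return 1.0 + overshoot
        return -_evaluate(surrogate, x, goals, goal_idx, hard)[0]

    best_free = None
    best_val = np.inf
    for start in starts:
        res = minimize(
            negative_D,
            start[:2],
            method="Nelder-Mead",
            options={"xatol": 1e-4, "fatol": 1e-9, "maxiter": 400},
        )
        if res.fun < best_val:
            best_val = float(res.fun)
            best_free = res.x
    assert best_free is not None
    a, b = best_free
    x = np.clip(np.array([a, b, total - a - b]), lo, hi)
    # restore the simplex sum after clipping via the free components
    x[1] = np.clip(total - x[0] - x[2], lo[1], hi[1])
    D, d, profile = _evaluate(surrogate, x, goals, goal_idx, hard)
    return DesirabilityResult(
        composition=Formulation(
            id="optimal", pegda=float(x[0]), peg400=float(x[1]), water=float(x[2])
        ),
        per_goal_d=d,
        overall_D=D,
        predicted_profile=tuple(float(profile[i]) for i in goal_idx),
        profile_times=tuple(g.time for g in goals),
        feasible=D > 0.0,
    )
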