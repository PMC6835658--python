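"""Synthetic formulations and dissolution curves with known ground truth.

The generator emulates the statistical structure the downstream analyses
assume: cumulative release follows a composition-linked power law
``Q(t) = k * t^n`` (the Korsmeyer-Peppas form), where the rate constant k
increases with PEG 400 (a diluent that loosens the crosslinked matrix) and
decreases with PEGDA (the crosslinker), and the release exponent n shifts
with water content while staying in the Fickian-to-anomalous band.  Replicate
noise of a few percent is added per time point, after which curves are made
non-decreasing and capped at 100 %.

Because the ground truth is an exact power law, kinetic fits on noiseless
profiles must recover k and n analytically — the basis of the parameter
recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import linprog

from .data import DesignBounds, DissolutionProfile, Formulation, PrintParameters

__all__ = [
    "GroundTruthModel",
    "SyntheticStudy",
    "exposure_time_rule",
    "generate_formulations",
    "simulate_dissolution",
    "generate_study",
    "DEFAULT_TIME_GRID",
]

#: Default sampling grid (hours): the study grid 1-8 h plus an early 0.5 h
#: point that stabilizes power-law fits.
DEFAULT_TIME_GRID = (0.5, 1.0, 2.0, 4.0, 6.0, 8.0)

#: Fixed minor components of every resin (% w/w).
RIBOFLAVIN_PCT = 0.10
IBUPROFEN_PCT = 5.00


@dataclass(frozen=True)
class GroundTruthModel:
    """Parameters of the generative release model.

    With composition in % w/w and time in hours:

        k(f) = k_base + k_peg * peg400 + k_pegda * pegda      [% / h^n]
        n(f) = clip(n_base + n_water * water, 0.05, 1.0)      [-]
        Q(t) = min(k * t^n + noise, 100), made non-decreasing

    Defaults are calibrated so that 8 h release spans roughly 38-91 % across
    the design region (fastest at maximal PEG 400, slowest at maximal PEGDA)
    and n stays in the 0.34-0.42 Fickian band.
    """

    k_base: float = 20.0  # %/h^n at zero PEG400/PEGDA contribution
    k_peg: float = 0.35  # per % PEG 400
    k_pegda: float = -0.10  # per % PEGDA
    n_base: float = 0.30
    n_water: float = 0.004  # per % water
    noise_sd: float = 2.0  # % released, per time point
    seed: int = 0

    def rate(self, f: Formulation) -> float:
        return self.k_base + self.k_peg * f.peg400 + self.k_pegda * f.pegda

    def exponent(self, f: Formulation) -> float:
        return float(np.clip(self.n_base + self.n_water * f.water, 0.05, 1.0))


@dataclass(frozen=True)
class SyntheticStudy:
    formulations: list[Formulation]
    print_parameters: dict[str, PrintParameters]
    profiles: dict[str, DissolutionProfile]
    truth: GroundTruthModel

    def __post_init__(self) -> None:
        ids = {f.id for f in self.formulations}
        if ids != set(self.profiles) or ids != set(self.print_parameters):
            raise ValueError(
                "every formulation needs exactly one profile and one "
                "print-parameter record"
            )


def exposure_time_rule(water: float) -> float:
    """Minimal per-layer exposure time (s) needed to cure a resin, by water %.

    Wetter resins photopolymerize more slowly, so curing time rises in steps
    with water content.  Monotone non-decreasing by construction.
    """
    if water < 0:
        raise ValueError("water content must be non-negative")
    if water < 7.5:
        return 100.0
    if water < 12.5:
        return 400.0
    if water < 17.5:
        return 500.0
    if water < 22.5:
        return 600.0
    return 800.0


def check_feasible(bounds: DesignBounds) -> None:
    """Raise if no composition satisfies the box bounds and mixture total.

    Solved as an explicit linear-program feasibility problem.
    """
    res = linprog(
        c=[0.0, 0.0, 0.0],
        A_eq=[[1.0, 1.0, 1.0]],
        b_eq=[bounds.mixture_total],
        bounds=list(zip(bounds.lowers, bounds.uppers)),
        method="highs",
    )
    if not res.success:
        raise ValueError(
            f"infeasible design bounds: no composition with components in "
            f"{list(zip(bounds.lowers, bounds.uppers))} sums to "
            f"{bounds.mixture_total}"
        )


def sample_simplex(
    bounds: DesignBounds, n: int, rng: np.random.Generator, max_tries: int = 100_000
) -> np.ndarray:
    """Uniform samples from the bounded simplex slice, by rejection.

    The first two components are drawn uniformly in their boxes and the third
    is the remainder; accepting only in-bounds remainders yields the uniform
    distribution on the 2D polytope.
    """
    check_feasible(bounds)
    lo, hi = bounds.lowers, bounds.uppers
    out = np.empty((n, 3))
    got = 0
    for _ in range(max_tries):
        if got >= n:
            break
        block = max(n - got, 16) * 4
        pegda = rng.uniform(lo[0], hi[0], size=block)
        peg = rng.uniform(lo[1], hi[1], size=block)
        water = bounds.mixture_total - pegda - peg
        ok = (water >= lo[2]) & (water <= hi[2])
        accepted = np.column_stack([pegda, peg, water])[ok]
        take = min(len(accepted), n - got)
        out[got : got + take] = accepted[:take]
        got += take
    if got < n:
        raise RuntimeError("rejection sampling failed; bounds nearly degenerate")
    return out


def generate_formulations(
    n: int,
    bounds: DesignBounds = DesignBounds(),
    mixture_total: Optional[float] = None,
    seed: int = 0,
    id_prefix: str = "S",
) -> list[Formulation]:
    """Draw ``n`` random in-bounds formulations (riboflavin/ibuprofen fixed)."""
    if mixture_total is not None:
        bounds = replace(bounds, mixture_total=mixture_total)
    rng = np.random.default_rng(seed)
    comps = sample_simplex(bounds, n, rng)
    return [
        Formulation(
            id=f"{id_prefix}{i + 1}",
            pegda=float(c[0]),
            peg400=float(c[1]),
            water=float(c[2]),
            riboflavin=RIBOFLAVIN_PCT,
            ibuprofen=IBUPROFEN_PCT,
        )
        for i, c in enumerate(comps)
    ]


def simulate_dissolution(
    f: Formulation,
    times: Sequence[float],
    truth: GroundTruthModel,
    seed: Optional[int] = None,
) -> DissolutionProfile:
    """Simulate one cumulative release curve for a formulation.

    The noiseless backbone is ``k(f) * t^n(f)``; Gaussian per-point noise of
    ``truth.noise_sd`` % is added, then the curve is clipped to [0, 100] and
    made non-decreasing with a running maximum (cumulative release cannot
    fall).  With ``noise_sd == 0`` the output equals the backbone exactly
    (apart from the 100 % cap).
    """
    t = np.asarray(times, dtype=float)
    if t.ndim != 1 or len(t) == 0 or np.any(t <= 0) or np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing and positive")
    k = truth.rate(f)
    if k <= 0:
        raise ValueError(
            f"formulation {f.id!r} yields non-positive release rate k={k:.3f}"
        )
    n_exp = truth.exponent(f)
    backbone = k * t**n_exp
    if truth.noise_sd > 0:
        rng = np.random.default_rng(truth.seed if seed is None else seed)
        noisy = backbone + rng.normal(0.0, truth.noise_sd, size=len(t))
    else:
        noisy = backbone
    released = np.maximum.accumulate(np.clip(noisy, 0.0, 100.0))
    return DissolutionProfile(times=tuple(t), released=tuple(released))


def generate_study(
    n: int,
    truth: GroundTruthModel = GroundTruthModel(),
    seed: int = 0,
    bounds: DesignBounds = DesignBounds(),
    times: Sequence[float] = DEFAULT_TIME_GRID,
) -> SyntheticStudy:
    """Generate a complete in-silico study of ``n`` formulations.

    Compositions are sampled from the bounded simplex, per-layer exposure
    times are assigned by :func:`exposure_time_rule`, and one dissolution
    profile per formulation is simulated with an independent noise stream
    derived from ``seed``.
    """
    root = np.random.SeedSequence(seed)
    form_seed, *profile_seeds = root.spawn(n + 1)
    comp_seed = int(form_seed.generate_state(1)[0] % (2**31))
    formulations = generate_formulations(n, bounds=bounds, seed=comp_seed)
    print_parameters = {
        f.id: PrintParameters(exposure_time=exposure_time_rule(f.water))
        for f in formulations
    }
    profiles = {
        f.id: simulate_dissolution(
            f, times, truth, seed=int(s.generate_state(1)[0] % (2**31))
        )
        for f, s in zip(formulations, profile_seeds)
    }
    return SyntheticStudy(
        formulations=formulations,
        print_parameters=print_parameters,
        profiles=profiles,
        truth=truth,
    )
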