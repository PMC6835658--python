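"""Core record types for photopolymer tablet formulations and their measurements.

A formulation is a resin recipe in % w/w: the photo-crosslinkable monomer
PEGDA, the non-crosslinking diluent PEG 400, water, a trace photo-initiator
(riboflavin) and the drug (ibuprofen).  The three variable components live on
a bounded mixture simplex; riboflavin and ibuprofen are held constant, so the
variable components sum to a fixed mixture total (~94.9 % w/w).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "Formulation",
    "PrintParameters",
    "DissolutionProfile",
    "TabletProperties",
    "DesignBounds",
    "STUDY_BOUNDS",
    "validate_formulation",
]

#: Allowed range for the total composition of a stored formulation.  Printed
#: recipes sum to 99.7-100.0 because each component is rounded to 2 decimals.
COMPOSITION_SUM_RANGE = (99.0, 100.5)


@dataclass(frozen=True)
class Formulation:
    """One resin composition in % w/w."""

    id: str
    pegda: float
    peg400: float
    water: float
    riboflavin: float = 0.10
    ibuprofen: float = 5.00

    def __post_init__(self) -> None:
        for name in ("pegda", "peg400", "water", "riboflavin", "ibuprofen"):
            value = getattr(self, name)
            if not math.isfinite(value) or value < 0:
                raise ValueError(
                    f"formulation {self.id!r}: component {name} must be a "
                    f"finite non-negative percentage, got {value!r}"
                )
        total = self.total
        lo, hi = COMPOSITION_SUM_RANGE
        if not (lo < total < hi):
            raise ValueError(
                f"formulation {self.id!r}: components sum to {total:.2f}%, "
                f"expected a value in ({lo}, {hi})"
            )

    @property
    def total(self) -> float:
        return self.pegda + self.peg400 + self.water + self.riboflavin + self.ibuprofen

    @property
    def components(self) -> tuple[float, float, float]:
        """The three variable mixture components (pegda, peg400, water)."""
        return (self.pegda, self.peg400, self.water)


@dataclass(frozen=True)
class PrintParameters:
    """DLP printing settings for one formulation."""

    exposure_time: float  # s, per ordinary layer
    bottom_exposure: float = 800.0  # s
    layer_thickness: float = 0.10  # mm
    bottom_layers: int = 10

    def __post_init__(self) -> None:
        if self.exposure_time <= 0:
            raise ValueError("exposure_time must be positive")
        if self.layer_thickness <= 0:
            raise ValueError("layer_thickness must be positive")


@dataclass(frozen=True)
class DissolutionProfile:
    """Cumulative % of dose released versus time (hours)."""

    times: tuple[float, ...]
    released: tuple[float, ...]
    sd: Optional[tuple[float, ...]] = None

    def __post_init__(self) -> None:
        times = tuple(float(t) for t in self.times)
        released = tuple(float(q) for q in self.released)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "released", released)
        if len(times) != len(released):
            raise ValueError("times and released must have equal length")
        if self.sd is not None:
            sd = tuple(float(s) for s in self.sd)
            object.__setattr__(self, "sd", sd)
            if len(sd) != len(times):
                raise ValueError("sd must match times in length")
        if any(t <= 0 for t in times):
            raise ValueError("all sampling times must be positive")
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("sampling times must be strictly increasing")
        if any(not (0.0 <= q <= 110.0) for q in released):
            raise ValueError("released values must lie in [0, 110] %")

    def __len__(self) -> int:
        return len(self.times)

    @property
    def times_array(self) -> np.ndarray:
        return np.asarray(self.times, dtype=float)

    @property
    def released_array(self) -> np.ndarray:
        return np.asarray(self.released, dtype=float)


@dataclass(frozen=True)
class TabletProperties:
    """Measured physical properties of a printed tablet.

    Hardness may be missing: very elastic tablets cannot be broken by the
    hardness tester, so no breaking force can be recorded.
    """

    weight: float  # mg
    diameter: float  # mm
    thickness: float  # mm
    hardness: Optional[float]  # N, None when not determined
    drug_load: float  # mg

    def __post_init__(self) -> None:
        for name in ("weight", "diameter", "thickness", "drug_load"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.hardness is not None and self.hardness <= 0:
            raise ValueError("hardness, when present, must be positive")


@dataclass(frozen=True)
class DesignBounds:
    """Box bounds on the three variable mixture components.

    The feasible region is the slice of the box where the components sum to
    ``mixture_total`` — a (bounded) 2-simplex in composition space.
    """

    pegda: tuple[float, float] = (30.0, 74.6)
    peg400: tuple[float, float] = (10.0, 54.6)
    water: tuple[float, float] = (10.0, 30.0)
    mixture_total: float = 94.9

    def __post_init__(self) -> None:
        for name in ("pegda", "peg400", "water"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name}: lower bound {lo} exceeds upper {hi}")

    @property
    def lowers(self) -> np.ndarray:
        return np.array([self.pegda[0], self.peg400[0], self.water[0]])

    @property
    def uppers(self) -> np.ndarray:
        return np.array([self.pegda[1], self.peg400[1], self.water[1]])

    def contains(self, components: Sequence[float], tol: float = 1e-9) -> bool:
        x = np.asarray(components, dtype=float)
        return bool(
            np.all(x >= self.lowers - tol) and np.all(x <= self.uppers + tol)
        )


#: Component limits used for the printed study design.
STUDY_BOUNDS = DesignBounds()


def validate_formulation(
    f: Formulation, bounds: DesignBounds = STUDY_BOUNDS
) -> list[str]:
    """Check a formulation against design bounds; violations are data, not errors.

    Returns one human-readable message per violated bound; an empty list means
    the composition is a valid design point.
    """
    violations: list[str] = []
    for name, value in zip(("pegda", "peg400", "water"), f.components):
        lo, hi = getattr(bounds, name)
        if value < lo:
            violations.append(
                f"{name} = {value:.2f}% below lower bound {lo:.2f}%"
            )
        elif value > hi:
            violations.append(
                f"{name} = {value:.2f}% above upper bound {hi:.2f}%"
            )
    return violations
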