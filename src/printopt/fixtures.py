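"""Built-in reference dataset for the ibuprofen DLP printlet study.

Fifteen resin formulations (eleven design points F1-F11, three external test
formulations, one drug-free placebo), their printing settings, the measured
tablet properties of the design points, and the dissolution comparison for
the optimized formulation (experimental release versus the release predicted
by the two surrogate networks).  These records drive the worked examples and
the desk-scale reproduction in the acceptance tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import DissolutionProfile, Formulation, PrintParameters, TabletProperties

__all__ = ["FixtureBundle", "OptimalComparison", "builtin_fixtures", "DESIGN_IDS"]

#: Identifiers of the D-optimal design points (the rows used for model fitting).
DESIGN_IDS = tuple(f"F{i}" for i in range(1, 12))

# id: (pegda, peg400, water, riboflavin, ibuprofen), % w/w
_FORMULATIONS = {
    "F1": (32.10, 32.60, 30.00, 0.10, 5.00),
    "F2": (30.00, 44.10, 20.50, 0.10, 5.00),
    "F3": (74.60, 10.00, 10.10, 0.10, 5.00),
    "F4": (62.40, 21.80, 10.50, 0.10, 5.00),
    "F5": (50.60, 34.00, 10.00, 0.10, 5.00),
    "F6": (65.80, 11.20, 17.70, 0.10, 5.00),
    "F7": (30.00, 54.60, 10.00, 0.10, 5.00),
    "F8": (58.10, 10.00, 26.60, 0.10, 5.00),
    "F9": (39.30, 45.30, 10.00, 0.10, 5.00),
    "F10": (46.20, 23.10, 25.40, 0.10, 5.00),
    "F11": (40.40, 35.60, 18.70, 0.10, 5.00),
    "Test 1": (35.00, 47.90, 12.00, 0.10, 5.00),
    "Test 2": (55.00, 24.90, 15.00, 0.10, 5.00),
    "Test 3": (65.00, 7.90, 22.00, 0.10, 5.00),
    "F placebo": (42.50, 42.40, 15.00, 0.10, 0.00),
}

# id: exposure time (s); all rows share bottom exposure 800 s, 0.10 mm layers,
# 10 bottom layers
_EXPOSURE = {
    "F1": 800.0, "F2": 800.0, "F3": 400.0, "F4": 400.0, "F5": 500.0,
    "F6": 600.0, "F7": 400.0, "F8": 800.0, "F9": 400.0, "F10": 800.0,
    "F11": 600.0, "Test 1": 400.0, "Test 2": 500.0, "Test 3": 600.0,
    "F placebo": 600.0,
}

# id: (weight mg, diameter mm, thickness mm, hardness N or None, drug load mg)
_PROPERTIES = {
    "F1": (387.00, 11.13, 3.00, 47.33, 24.11),
    "F2": (378.00, 10.86, 3.09, 32.00, 23.00),
    "F3": (323.40, 10.81, 3.00, 108.33, 15.00),
    "F4": (296.70, 10.17, 3.02, 92.33, 14.40),
    "F5": (354.40, 10.55, 3.00, 33.00, 22.30),
    "F6": (278.90, 10.04, 3.00, 132.33, 18.30),
    "F7": (345.10, 10.52, 2.99, None, 21.70),  # too elastic to break
    "F8": (400.10, 12.40, 2.97, 29.67, 27.10),
    "F9": (340.50, 10.60, 2.94, 19.00, 23.00),
    "F10": (375.00, 11.53, 2.92, 37.00, 25.80),
    "F11": (377.50, 11.40, 2.99, 35.00, 25.50),
}

# Optimal formulation: cumulative % released at 2/4/6/8 h.
_OPT_TIMES = (2.0, 4.0, 6.0, 8.0)
_OPT_EXPERIMENTAL = (29.85, 51.18, 65.73, 76.60)
_OPT_PREDICTED_NN1 = (41.96, 63.34, 70.00, 79.99)
_OPT_PREDICTED_NN2 = (45.37, 62.77, 76.66, 88.46)

#: Composition of the optimized formulation reported by the original study,
#: used as a reference point when benchmarking the desirability optimizer.
OPTIMAL_COMPOSITION = Formulation(
    id="F optimal", pegda=30.00, peg400=52.89, water=12.02
)

# Published per-formulation release-kinetics summaries: best-model rate
# constants are in per-minute units; n is the power-law release exponent.
# These serve as classification fixtures (the underlying raw curves are not
# part of this dataset).
KINETIC_EXPONENTS = {
    "F1": 0.3588, "F2": 0.3843, "F3": 0.3619, "F4": 0.4024, "F5": 0.4609,
    "F6": 0.4895, "F7": 0.4767, "F8": 0.3671, "F9": 0.4027, "F10": 0.3489,
    "F11": 0.4147, "Test 1": 0.5535, "Test 2": 0.5656, "Test 3": 0.5144,
    "F optimal": 0.4872,
}


@dataclass(frozen=True)
class OptimalComparison:
    """Experimental vs surrogate-predicted release for the optimized tablet."""

    times: tuple[float, ...]
    experimental: tuple[float, ...]
    predicted_nn1: tuple[float, ...]
    predicted_nn2: tuple[float, ...]

    @property
    def experimental_profile(self) -> DissolutionProfile:
        return DissolutionProfile(self.times, self.experimental)


@dataclass(frozen=True)
class FixtureBundle:
    formulations: dict[str, Formulation]
    print_parameters: dict[str, PrintParameters]
    tablet_properties: dict[str, TabletProperties]
    optimal_comparison: OptimalComparison

    def design_formulations(self) -> list[Formulation]:
        """The eleven design-point formulations, in design order."""
        return [self.formulations[i] for i in DESIGN_IDS]

    def design_matrix(self) -> np.ndarray:
        """(11, 3) array of variable components for the design points."""
        return np.array([f.components for f in self.design_formulations()])

    def response(self, name: str) -> dict[str, float | None]:
        """Per-design-point response values: 'weight', 'hardness' or 'drug_load'."""
        return {
            i: getattr(self.tablet_properties[i], name) for i in DESIGN_IDS
        }


def builtin_fixtures() -> FixtureBundle:
    """Return the bundled reference dataset as validated records."""
    formulations = {
        fid: Formulation(fid, *vals) for fid, vals in _FORMULATIONS.items()
    }
    print_parameters = {
        fid: PrintParameters(exposure_time=t) for fid, t in _EXPOSURE.items()
    }
    tablet_properties = {
        fid: TabletProperties(
            weight=w, diameter=d, thickness=th, hardness=h, drug_load=dl
        )
        for fid, (w, d, th, h, dl) in _PROPERTIES.items()
    }
    comparison = OptimalComparison(
        times=_OPT_TIMES,
        experimental=_OPT_EXPERIMENTAL,
        predicted_nn1=_OPT_PREDICTED_NN1,
        predicted_nn2=_OPT_PREDICTED_NN2,
    )
    return FixtureBundle(
        formulations=formulations,
        print_parameters=print_parameters,
        tablet_properties=tablet_properties,
        optimal_comparison=comparison,
    )
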