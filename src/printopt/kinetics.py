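"""Drug-release kinetic models: zero-order, first-order, Higuchi, power law.

Each model is fitted on its classical linearized form with the intercept
fixed where the model form implies one:

    zero order       Q = k0·t               (through origin, Q vs t)
    first order      ln(100−Q) = ln100 − k1·t   (fixed intercept ln 100)
    Higuchi          Q = kh·√t              (through origin, Q vs √t)
    Korsmeyer–Peppas ln Q = ln kkp + n·ln t (free intercept; points Q ≤ 60 %)

Rate constants are reported per *minute* (k0 %/min, k1 1/min, kh %/min^0.5,
kkp %/min^n); profile times in hours are converted internally.  R² is the
coefficient of determination of the linearized regression (1 − SSres/SStot
with mean-corrected SStot), the convention of dissolution-modeling software;
for poor through-origin fits it can be negative.

The power-law exponent n indicates the transport mechanism: n < 0.45 Fickian
diffusion, 0.45 ≤ n ≤ 0.89 anomalous (non-Fickian) transport, larger n
convection/relaxation-controlled transport.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import DissolutionProfile

__all__ = [
    "KineticFit",
    "fit_zero_order",
    "fit_first_order",
    "fit_higuchi",
    "fit_korsmeyer_peppas",
    "fit_all",
    "select_kinetic_model",
    "classify_mechanism",
    "MODEL_ORDER",
]

#: Simplicity order used to break R² ties (simplest first).
MODEL_ORDER = ("zero_order", "first_order", "higuchi", "korsmeyer_peppas")

#: Default upper release cutoff (%) for power-law fitting; the Q = k·t^n form
#: is only valid over the early portion of the curve.
KP_RELEASE_CUTOFF = 60.0

_MIN_PER_H = 60.0


@dataclass(frozen=True)
class KineticFit:
    model: str
    params: dict[str, float]
    r2: float
    n_points: int

    def __post_init__(self) -> None:
        if self.r2 > 1.0 + 1e-12:
            raise ValueError("r2 cannot exceed 1")
        if "n" in self.params and self.params["n"] <= 0:
            raise ValueError("release exponent must be positive")


def _usable(profile: DissolutionProfile, need_log_q: bool) -> tuple[np.ndarray, np.ndarray]:
    t = profile.times_array * _MIN_PER_H
    q = profile.released_array
    if np.any(q >= 100.0):
        raise ValueError(
            "released values must stay below 100 % within the fit window"
        )
    if need_log_q:
        keep = q > 0
        t, q = t[keep], q[keep]
    return t, q


def _r2_linearized(y: np.ndarray, fitted: np.ndarray) -> float:
    ss_res = float(np.sum((y - fitted) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        return 1.0 if ss_res < 1e-20 else -np.inf
    return 1.0 - ss_res / ss_tot


def fit_zero_order(profile: DissolutionProfile) -> KineticFit:
    """Constant-rate release: cumulative Q grows linearly with time."""
    t, q = _usable(profile, need_log_q=False)
    if len(t) < 2:
        raise ValueError("zero-order fit needs at least 2 points")
    k0 = float(t @ q / (t @ t))
    return KineticFit("zero_order", {"k0": k0}, _r2_linearized(q, k0 * t), len(t))


def fit_first_order(profile: DissolutionProfile) -> KineticFit:
    """Release rate proportional to drug remaining: Q = 100·(1 − e^(−k1·t))."""
    t, q = _usable(profile, need_log_q=False)
    if len(t) < 2:
        raise ValueError("first-order fit needs at least 2 points")
    y = np.log(100.0 - q)
    # slope through the fixed intercept ln(100)
    k1 = float(-(t @ (y - np.log(100.0))) / (t @ t))
    fitted = np.log(100.0) - k1 * t
    return KineticFit("first_order", {"k1": k1}, _r2_linearized(y, fitted), len(t))


def fit_higuchi(profile: DissolutionProfile) -> KineticFit:
    """Matrix-diffusion release: Q proportional to the square root of time."""
    t, q = _usable(profile, need_log_q=False)
    if len(t) < 2:
        raise ValueError("Higuchi fit needs at least 2 points")
    s = np.sqrt(t)
    kh = float(s @ q / (s @ s))
    return KineticFit("higuchi", {"kh": kh}, _r2_linearized(q, kh * s), len(t))


def fit_korsmeyer_peppas(
    profile: DissolutionProfile, release_cutoff: float = KP_RELEASE_CUTOFF
) -> KineticFit:
    """Power-law release Q = kkp·t^n, fitted on ln Q vs ln t for Q ≤ cutoff."""
    t, q = _usable(profile, need_log_q=True)
    keep = q <= release_cutoff
    t, q = t[keep], q[keep]
    if len(t) < 3:
        raise ValueError(
            f"power-law fit needs at least 3 points with 0 < Q <= {release_cutoff}"
        )
    ln_t, ln_q = np.log(t), np.log(q)
    slope, intercept = np.polyfit(ln_t, ln_q, 1)
    fitted = intercept + slope * ln_t
    return KineticFit(
        "korsmeyer_peppas",
        {"kkp": float(np.exp(intercept)), "n": float(slope)},
        _r2_linearized(ln_q, fitted),
        len(t),
    )


def fit_all(profile: DissolutionProfile) -> dict[str, KineticFit]:
    """Fit every model that succeeds on this profile; failures are omitted."""
    fits: dict[str, KineticFit] = {}
    for name, fn in (
        ("zero_order", fit_zero_order),
        ("first_order", fit_first_order),
        ("higuchi", fit_higuchi),
        ("korsmeyer_peppas", fit_korsmeyer_peppas),
    ):
        try:
            fits[name] = fn(profile)
        except ValueError:
            continue
    return fits


def select_kinetic_model(fits: dict[str, KineticFit]) -> KineticFit:
    """Highest R² wins; exact ties go to the simpler model."""
    if not fits:
        raise ValueError("no successful kinetic fit to select from")
    return max(
        fits.values(),
        key=lambda f: (f.r2, -MODEL_ORDER.index(f.model)),
    )


def classify_mechanism(n: float) -> str:
    """Transport mechanism implied by the power-law release exponent.

    For the thin-film/cylinder convention used here: n below 0.45 is Fickian
    diffusion; 0.45 up to and including 0.89 is anomalous transport; larger
    values indicate relaxation-controlled (super case II) transport — a label
    outside the band the classification was established for, so treat it as
    an extrapolation.
    """
    if n <= 0:
        raise ValueError("release exponent must be positive")
    if n < 0.45:
        return "Fickian diffusion"
    if n <= 0.89:
        return "anomalous transport"
    return "super case II transport (extrapolated)"
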