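"""Model-independent dissolution-profile comparison: f1, f2 and observed-vs-predicted R².

The regulatory difference factor f1 and similarity factor f2 compare a test
profile T against a reference profile R over n shared sampling times:

    f1 = 100 · Σ|R_t − T_t| / ΣR_t
    f2 = 50 · log10( 100 / sqrt(1 + (1/n)·Σ(R_t − T_t)²) )

Profiles are conventionally declared similar when f1 ≤ 15 and f2 ≥ 50
(identical profiles give f1 = 0, f2 = 100).  By default every supplied time
point enters f2; the regulatory practice of truncating after the first point
above 85 % release is available as an option.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "ProfileComparison",
    "f1_difference",
    "f2_similarity",
    "r2_obs_pred",
    "similarity_verdict",
]


@dataclass(frozen=True)
class ProfileComparison:
    """Paired reference (experimental) and test (predicted) release values."""

    times: tuple[float, ...]
    reference: tuple[float, ...]
    test: tuple[float, ...]

    def __post_init__(self) -> None:
        if not (len(self.times) == len(self.reference) == len(self.test)):
            raise ValueError("times, reference and test must have equal length")
        if len(self.times) < 1:
            raise ValueError("at least one shared sampling time is required")

    @property
    def n(self) -> int:
        return len(self.times)

    @classmethod
    def from_arrays(
        cls, times: Sequence[float], reference: Sequence[float], test: Sequence[float]
    ) -> "ProfileComparison":
        return cls(tuple(times), tuple(reference), tuple(test))

    def _truncated(self, truncate_after_85: bool) -> tuple[np.ndarray, np.ndarray]:
        r = np.asarray(self.reference, dtype=float)
        t = np.asarray(self.test, dtype=float)
        if truncate_after_85:
            above = np.nonzero(r > 85.0)[0]
            if len(above) > 0:
                stop = above[0] + 1  # keep one point above 85 %
                r, t = r[:stop], t[:stop]
        return r, t


def f1_difference(cmp: ProfileComparison) -> float:
    """Difference factor; asymmetric — the reference supplies the denominator."""
    r = np.asarray(cmp.reference, dtype=float)
    t = np.asarray(cmp.test, dtype=float)
    denom = float(np.sum(r))
    if denom <= 0:
        raise ValueError("f1 undefined: reference profile sums to zero")
    return float(100.0 * np.sum(np.abs(r - t)) / denom)


def f2_similarity(cmp: ProfileComparison, truncate_after_85: bool = False) -> float:
    """Similarity factor on the shared time points (all points by default)."""
    r, t = cmp._truncated(truncate_after_85)
    msd = float(np.mean((r - t) ** 2))
    return float(50.0 * np.log10(100.0 / np.sqrt(1.0 + msd)))


def r2_obs_pred(cmp: ProfileComparison) -> float:
    """Squared Pearson correlation between observed and predicted release."""
    r = np.asarray(cmp.reference, dtype=float)
    t = np.asarray(cmp.test, dtype=float)
    if cmp.n < 2:
        raise ValueError("observed-vs-predicted R² needs at least 2 points")
    if np.ptp(r) == 0 or np.ptp(t) == 0:
        raise ValueError("correlation undefined for a constant series")
    return float(np.corrcoef(r, t)[0, 1] ** 2)


def similarity_verdict(f1: float, f2: float) -> str:
    """Regulatory call: 'similar' iff f1 ≤ 15 and f2 ≥ 50."""
    return "similar" if (f1 <= 15.0 and f2 >= 50.0) else "not similar"
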