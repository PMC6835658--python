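"""Scheffé mixture-polynomial fitting, selection statistics and D-optimal design.

Because the three variable components sum to a (near-)constant mixture total,
response models use the Scheffé canonical form: polynomials in the component
percentages with *no intercept* (the constant is absorbed by the sum
constraint).  Model adequacy is judged the way mixture-design software does:
R² against the mean-corrected total sum of squares, adjusted R² with model
degrees of freedom ``n_terms - 1`` (one parameter is spent on the constraint),
and predicted R² from the leave-one-out PRESS statistic computed via the hat
matrix.

Design generation uses the Fedorov exchange algorithm over a candidate set of
polytope vertices, edge midpoints, the centroid and random in-bounds fill,
maximizing ``det(X'X)`` for the requested Scheffé degree.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np

from .data import DesignBounds, Formulation
from .synthetic import check_feasible, sample_simplex

__all__ = [
    "DEGREES",
    "MixtureModelFit",
    "ModelSelection",
    "scheffe_terms",
    "scheffe_matrix",
    "fit_mixture_model",
    "press_loo",
    "select_model",
    "doptimal_design",
    "fedorov_exchange",
    "polytope_vertices",
]

DEGREES = ("linear", "quadratic", "special_cubic", "full_cubic")

_COMPONENT_NAMES = ("pegda", "peg400", "water")


def scheffe_terms(
    components: Sequence[float], degree: str,
    names: Sequence[str] = _COMPONENT_NAMES,
) -> tuple[np.ndarray, list[str]]:
    """Evaluate the Scheffé canonical terms of one composition.

    linear:        x1, x2, x3
    quadratic:     + x1·x2, x1·x3, x2·x3
    special_cubic: + x1·x2·x3
    full_cubic:    + x1·x2·(x1−x2), x1·x3·(x1−x3), x2·x3·(x2−x3)

    No intercept term is ever included.
    """
    x = np.asarray(components, dtype=float)
    if x.shape != (3,):
        raise ValueError("expected exactly 3 mixture components")
    if degree not in DEGREES:
        raise ValueError(f"unknown degree {degree!r}; expected one of {DEGREES}")
    a, b, c = names
    values = list(x)
    labels = [a, b, c]
    if degree in ("quadratic", "special_cubic", "full_cubic"):
        for (i, j) in ((0, 1), (0, 2), (1, 2)):
            values.append(x[i] * x[j])
            labels.append(f"{names[i]}*{names[j]}")
    if degree in ("special_cubic", "full_cubic"):
        values.append(x[0] * x[1] * x[2])
        labels.append(f"{a}*{b}*{c}")
    if degree == "full_cubic":
        for (i, j) in ((0, 1), (0, 2), (1, 2)):
            values.append(x[i] * x[j] * (x[i] - x[j]))
            labels.append(f"{names[i]}*{names[j]}*({names[i]}-{names[j]})")
    return np.array(values), labels


def scheffe_matrix(
    compositions: np.ndarray, degree: str
) -> tuple[np.ndarray, list[str]]:
    """Model matrix (rows = compositions) for a Scheffé polynomial."""
    compositions = np.atleast_2d(np.asarray(compositions, dtype=float))
    rows = [scheffe_terms(row, degree) for row in compositions]
    return np.array([r[0] for r in rows]), rows[0][1]


@dataclass(frozen=True)
class MixtureModelFit:
    degree: str
    terms: tuple[str, ...]
    coefficients: tuple[float, ...]  # in actual % w/w units
    n_obs: int
    r2: float
    adj_r2: float
    pred_r2: float
    press: float
    residual_df: int
    ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if len(self.terms) != len(self.coefficients):
            raise ValueError("terms and coefficients must align")

    def coefficient(self, term: str) -> float:
        return self.coefficients[self.terms.index(term)]

    def predict(self, compositions: np.ndarray) -> np.ndarray:
        X, _ = scheffe_matrix(compositions, self.degree)
        return X @ np.asarray(self.coefficients)


def _design_and_response(
    formulations: Sequence[Formulation],
    response: Mapping[str, Optional[float]] | Sequence[Optional[float]],
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    if isinstance(response, Mapping):
        pairs = [(f, response.get(f.id)) for f in formulations]
    else:
        pairs = list(zip(formulations, response))
    kept = [(f, y) for f, y in pairs if y is not None and np.isfinite(y)]
    X = np.array([f.components for f, _ in kept])
    y = np.array([y for _, y in kept], dtype=float)
    ids = [f.id for f, _ in kept]
    return X, y, ids


def fit_mixture_model(
    formulations: Sequence[Formulation],
    response: Mapping[str, Optional[float]] | Sequence[Optional[float]],
    degree: str = "linear",
) -> MixtureModelFit:
    """No-intercept least squares of a response on Scheffé terms in actual % units.

    Rows with a missing response are dropped before fitting.  Raises
    ``np.linalg.LinAlgError`` when fewer usable rows remain than model terms.
    """
    comps, y, ids = _design_and_response(formulations, response)
    X, labels = scheffe_matrix(comps, degree)
    n, p = X.shape
    # A saturated model (n == p) interpolates the data: no residual df, no
    # out-of-sample prediction — reported as unavailable, like n.d. cells in
    # mixture-design software.
    if n <= p or np.linalg.matrix_rank(X) < p:
        raise np.linalg.LinAlgError(
            f"{degree} model has {p} terms but only {n} usable observations "
            "(saturated, underdetermined or rank-deficient)"
        )
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ beta
    resid = y - fitted
    ss_res = float(resid @ resid)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot
    # One model parameter is absorbed by the mixture-sum constraint, so the
    # model has p-1 effective df and the residual has n-p.
    residual_df = n - p
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / residual_df if residual_df > 0 else np.nan
    press, pred_r2 = press_loo(X, y, beta=beta)
    return MixtureModelFit(
        degree=degree,
        terms=tuple(labels),
        coefficients=tuple(float(b) for b in beta),
        n_obs=n,
        r2=r2,
        adj_r2=float(adj_r2),
        pred_r2=pred_r2,
        press=press,
        residual_df=residual_df,
        ids=tuple(ids),
    )


def press_loo(
    X: np.ndarray, y: np.ndarray, beta: Optional[np.ndarray] = None
) -> tuple[float, float]:
    """Leave-one-out PRESS and predicted R² via the hat-matrix identity.

    PRESS = Σ (e_i / (1 - h_ii))² where h_ii are hat diagonals; this equals
    explicitly refitting with each observation held out.  Predicted R² is
    1 - PRESS / SS_total (mean-corrected) and can be negative.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if beta is None:
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    # hat diagonal via economy QR: h_ii = ||q_i||^2
    q, _ = np.linalg.qr(X)
    h = np.sum(q**2, axis=1)
    if np.any(h >= 1.0 - 1e-10):
        raise ValueError(
            "a leverage of 1 was found: that observation cannot be predicted "
            "out-of-sample (leave-one-out subfit is rank-deficient)"
        )
    press = float(np.sum((resid / (1.0 - h)) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    return press, 1.0 - press / ss_tot


@dataclass(frozen=True)
class ModelSelection:
    chosen: MixtureModelFit
    candidates: dict[str, MixtureModelFit]
    unavailable: dict[str, str]  # degree -> reason
    rationale: str


def select_model(fits: Mapping[str, MixtureModelFit | None] | Sequence[MixtureModelFit]) -> ModelSelection:
    """Pick the fit jointly maximizing adjusted and predicted R².

    The criterion is the larger of min(adj R², pred R²), with predicted R²
    and then adjusted R² breaking ties.  Maximizing the minimum rejects
    overfitted polynomials whose adjusted R² looks good while their
    leave-one-out performance collapses (strongly negative predicted R²),
    which is how mixture-design practice reads the two statistics together.
    Degrees that could not be fitted (too few observations for the term
    count) are recorded as unavailable rather than failing the selection.
    """
    if not isinstance(fits, Mapping):
        fits = {f.degree: f for f in fits}
    candidates: dict[str, MixtureModelFit] = {}
    unavailable: dict[str, str] = {}
    for degree, fit in fits.items():
        if fit is None:
            unavailable[degree] = "not fitted (insufficient observations)"
        elif fit.residual_df < 1 or not np.isfinite(fit.adj_r2):
            unavailable[degree] = "no residual degrees of freedom"
        else:
            candidates[degree] = fit
    if not candidates:
        raise ValueError("no fitted model available for selection")
    best = max(
        candidates.values(),
        key=lambda f: (min(f.adj_r2, f.pred_r2), f.pred_r2, f.adj_r2),
    )
    rationale = (
        f"selected {best.degree}: adj R2 = {best.adj_r2:.4f}, "
        f"pred R2 = {best.pred_r2:.4f}"
        + (f"; unavailable: {sorted(unavailable)}" if unavailable else "")
    )
    return ModelSelection(
        chosen=best, candidates=candidates, unavailable=unavailable,
        rationale=rationale,
    )


def polytope_vertices(bounds: DesignBounds) -> np.ndarray:
    """Vertices of the bounded mixture simplex.

    On the 2D slice {x1+x2+x3 = total}, every vertex has two box constraints
    active: enumerate component pairs at their bounds and keep remainders that
    land inside the third component's box.
    """
    lo, hi = bounds.lowers, bounds.uppers
    verts = []
    for i, j in itertools.combinations(range(3), 2):
        k = 3 - i - j
        for bi in (lo[i], hi[i]):
            for bj in (lo[j], hi[j]):
                rem = bounds.mixture_total - bi - bj
                if lo[k] - 1e-9 <= rem <= hi[k] + 1e-9:
                    v = np.empty(3)
                    v[i], v[j], v[k] = bi, bj, np.clip(rem, lo[k], hi[k])
                    verts.append(v)
    if not verts:
        raise ValueError("bounds admit no vertices; check feasibility")
    uniq = np.unique(np.round(np.array(verts), 9), axis=0)
    return uniq


def _candidate_set(
    bounds: DesignBounds, n_random: int, rng: np.random.Generator
) -> np.ndarray:
    verts = polytope_vertices(bounds)
    mids = [(a + b) / 2.0 for a, b in itertools.combinations(verts, 2)]
    centroid = verts.mean(axis=0)
    fill = sample_simplex(bounds, n_random, rng) if n_random > 0 else np.empty((0, 3))
    cands = np.vstack([verts, mids, [centroid], fill])
    return np.unique(np.round(cands, 9), axis=0)


def fedorov_exchange(
    Xc: np.ndarray,
    n_runs: int,
    rng: np.random.Generator,
    max_iter: int = 50,
) -> tuple[list[int], list[float]]:
    """Greedy single-point exchange maximizing det(X'X) over candidate rows.

    Returns the selected candidate indices and the determinant after each
    accepted swap (non-decreasing by construction of the acceptance rule).
    """

    def det_of(idx: list[int]) -> float:
        X = Xc[idx]
        return float(np.linalg.det(X.T @ X))

    best_idx: list[int] | None = None
    for _ in range(200):
        idx = list(rng.choice(len(Xc), size=n_runs, replace=False))
        if det_of(idx) > 0:
            best_idx = idx
            break
    if best_idx is None:
        raise np.linalg.LinAlgError("could not find a non-singular starting design")

    best_det = det_of(best_idx)
    history = [best_det]
    for _ in range(max_iter):
        improved = False
        for pos in range(n_runs):
            trial = list(best_idx)
            gains = []
            for c in range(len(Xc)):
                if c in best_idx:
                    continue
                trial[pos] = c
                d = det_of(trial)
                if d > best_det * (1 + 1e-12):
                    gains.append((d, c))
            if gains:
                d, c = max(gains)
                best_idx[pos] = c
                best_det = d
                history.append(d)
                improved = True
        if not improved:
            break
    return best_idx, history


def doptimal_design(
    bounds: DesignBounds,
    n_runs: int,
    degree: str = "linear",
    n_candidates: int = 200,
    seed: int = 0,
    max_iter: int = 50,
    id_prefix: str = "D",
) -> list[Formulation]:
    """Select ``n_runs`` compositions maximizing det(X'X) by Fedorov exchange.

    The candidate set contains the polytope vertices, all pairwise vertex
    midpoints, the centroid, and ``n_candidates`` random in-bounds fill
    points.  Starting from a random non-singular subset, single-point
    exchanges are applied greedily while they increase the determinant.
    Deterministic for a given seed.
    """
    check_feasible(bounds)
    rng = np.random.default_rng(seed)
    cands = _candidate_set(bounds, n_candidates, rng)
    Xc, _ = scheffe_matrix(cands, degree)
    p = Xc.shape[1]
    if n_runs < p:
        raise np.linalg.LinAlgError(
            f"n_runs={n_runs} cannot support a {degree} model with {p} terms"
        )

    best_idx, _ = fedorov_exchange(Xc, n_runs, rng, max_iter=max_iter)
    chosen = cands[sorted(best_idx, key=lambda i: tuple(cands[i]))]
    return [
        Formulation(
            id=f"{id_prefix}{i + 1}",
            pegda=float(c[0]), peg400=float(c[1]), water=float(c[2]),
        )
        for i, c in enumerate(chosen)
    ]
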