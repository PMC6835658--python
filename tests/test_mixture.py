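"""Scheffé mixture fitting, selection statistics and D-optimal design."""

import numpy as np
import pytest

from printopt.data import DesignBounds, Formulation
from printopt.mixture import (
    DEGREES,
    MixtureModelFit,
    doptimal_design,
    fedorov_exchange,
    fit_mixture_model,
    polytope_vertices,
    press_loo,
    scheffe_matrix,
    scheffe_terms,
    select_model,
    _candidate_set,
)


class TestScheffeTerms:
    def test_linear_is_identity_on_components(self):
        values, labels = scheffe_terms((1.0, 0.0, 0.0), "linear")
        np.testing.assert_array_equal(values, [1.0, 0.0, 0.0])
        assert labels == ["pegda", "peg400", "water"]

    def test_quadratic_products(self):
        values, _ = scheffe_terms((2.0, 3.0, 5.0), "quadratic")
        np.testing.assert_array_equal(values, [2, 3, 5, 6, 10, 15])

    def test_full_cubic_difference_terms_vanish_at_equal_components(self):
        values, labels = scheffe_terms((1.0, 1.0, 1.0), "full_cubic")
        assert len(values) == 10
        np.testing.assert_array_equal(values[-3:], [0.0, 0.0, 0.0])

    def test_no_intercept_column_ever(self):
        for degree in DEGREES:
            X, _ = scheffe_matrix(np.array([[2.0, 3.0, 5.0], [1.0, 1.0, 8.0]]), degree)
            assert not np.any(np.all(X == 1.0, axis=0))

    def test_unknown_degree_rejected(self):
        with pytest.raises(ValueError, match="degree"):
            scheffe_terms((1.0, 2.0, 3.0), "quartic")


def _exact_linear_case(bundle):
    design = bundle.design_formulations()
    response = {
        f.id: 2 * f.pegda + 3 * f.peg400 + 4 * f.water for f in design
    }
    return design, response


class TestFitMixtureModel:
    def test_exact_linear_response_recovered_to_machine_precision(self, bundle):
        design, response = _exact_linear_case(bundle)
        fit = fit_mixture_model(design, response, "linear")
        np.testing.assert_allclose(fit.coefficients, [2.0, 3.0, 4.0], rtol=1e-12)
        assert fit.press == pytest.approx(0.0, abs=1e-12)
        assert fit.pred_r2 == pytest.approx(1.0)

    def test_missing_responses_are_dropped(self, bundle):
        fit = fit_mixture_model(
            bundle.design_formulations(), bundle.response("hardness"), "linear"
        )
        assert fit.n_obs == 10
        assert "F7" not in fit.ids

    def test_saturated_model_raises_rank_error(self, bundle):
        # hardness has 10 usable rows; the 10-term full cubic interpolates
        with pytest.raises(np.linalg.LinAlgError):
            fit_mixture_model(
                bundle.design_formulations(), bundle.response("hardness"),
                "full_cubic",
            )

    def test_reparametrization_invariance_of_fitted_values(self, bundle):
        design = bundle.design_formulations()
        response = bundle.response("weight")
        fit_pct = fit_mixture_model(design, response, "linear")
        X = np.array([f.components for f in design])
        y = np.array([response[f.id] for f in design])
        beta_scaled, *_ = np.linalg.lstsq(X / 100.0, y, rcond=None)
        np.testing.assert_allclose(
            (X / 100.0) @ beta_scaled, X @ np.array(fit_pct.coefficients), rtol=1e-9
        )
        np.testing.assert_allclose(
            beta_scaled, 100.0 * np.array(fit_pct.coefficients), rtol=1e-9
        )

    def test_statistic_ordering_on_every_fixture_response(self, bundle):
        design = bundle.design_formulations()
        for name in ("weight", "hardness", "drug_load"):
            for degree in ("linear", "quadratic", "special_cubic"):
                fit = fit_mixture_model(design, bundle.response(name), degree)
                assert fit.pred_r2 <= fit.adj_r2 + 1e-12
                assert fit.adj_r2 <= fit.r2 + 1e-12

    def test_fixture_r2_matches_reported_range(self, bundle):
        design = bundle.design_formulations()
        r2 = {
            name: fit_mixture_model(design, bundle.response(name), "linear").r2
            for name in ("weight", "hardness", "drug_load")
        }
        assert r2["weight"] == pytest.approx(0.586, abs=0.005)
        assert r2["hardness"] == pytest.approx(0.578, abs=0.005)
        assert r2["drug_load"] == pytest.approx(0.615, abs=0.005)


class TestPressLoo:
    def test_hat_shortcut_equals_explicit_refits(self, bundle):
        design = bundle.design_formulations()
        for name in ("weight", "hardness", "drug_load"):
            response = bundle.response(name)
            pairs = [(f, response[f.id]) for f in design if response[f.id] is not None]
            X = np.array([f.components for f, _ in pairs])
            y = np.array([v for _, v in pairs])
            press_hat, _ = press_loo(X, y)
            press_brute = 0.0
            for i in range(len(y)):
                mask = np.arange(len(y)) != i
                beta, *_ = np.linalg.lstsq(X[mask], y[mask], rcond=None)
                press_brute += (y[i] - X[i] @ beta) ** 2
            assert press_hat == pytest.approx(press_brute, rel=1e-8)

    def test_matches_statsmodels_ols_influence(self, bundle):
        statsmodels = pytest.importorskip("statsmodels.api")
        design = bundle.design_formulations()
        response = bundle.response("weight")
        X = np.array([f.components for f in design])
        y = np.array([response[f.id] for f in design])
        results = statsmodels.OLS(y, X).fit()
        influence = results.get_influence()
        press_ref = float(np.sum(influence.resid_press**2))
        press_ours, _ = press_loo(X, y)
        assert press_ours == pytest.approx(press_ref, rel=1e-10)

    def test_unit_leverage_is_an_error(self):
        with pytest.raises(ValueError, match="leverage"):
            press_loo(np.eye(2), np.array([1.0, 2.0]))


class TestSelectModel:
    @staticmethod
    def _fit(degree, adj, pred):
        return MixtureModelFit(
            degree=degree, terms=("a", "b", "c"), coefficients=(1.0, 1.0, 1.0),
            n_obs=11, r2=max(adj, pred), adj_r2=adj, pred_r2=pred,
            press=1.0, residual_df=8,
        )

    def test_overfit_high_adj_with_collapsed_pred_loses(self):
        # mirror of the reference study's summary table: the cubic has the
        # best adjusted R-squared but a disastrous leave-one-out performance
        fits = {
            "linear": self._fit("linear", 0.4828, 0.2042),
            "quadratic": self._fit("quadratic", 0.40, -2.6704),
            "special_cubic": self._fit("special_cubic", 0.0573, -4.744),
            "full_cubic": self._fit("full_cubic", 0.5331, -15888.43),
        }
        assert select_model(fits).chosen.degree == "linear"

    def test_single_candidate_wins(self):
        fits = {"linear": self._fit("linear", 0.5, 0.3)}
        assert select_model(fits).chosen.degree == "linear"

    def test_equal_adj_ties_break_on_pred(self):
        fits = {
            "linear": self._fit("linear", 0.5, 0.30),
            "quadratic": self._fit("quadratic", 0.5, 0.45),
        }
        assert select_model(fits).chosen.degree == "quadratic"

    def test_unavailable_degrees_are_recorded(self):
        fits = {"linear": self._fit("linear", 0.5, 0.3), "full_cubic": None}
        selection = select_model(fits)
        assert "full_cubic" in selection.unavailable
        assert selection.chosen.degree == "linear"

    def test_no_candidate_raises(self):
        with pytest.raises(ValueError):
            select_model({"linear": None})


class TestDOptimalDesign:
    def test_three_run_linear_design_on_full_simplex_picks_vertices(self):
        bounds = DesignBounds(
            pegda=(0.0, 94.9), peg400=(0.0, 94.9), water=(0.0, 94.9)
        )
        design = doptimal_design(bounds, 3, "linear", seed=1)
        comps = sorted(f.components for f in design)
        assert comps == [
            (0.0, 0.0, 94.9), (0.0, 94.9, 0.0), (94.9, 0.0, 0.0)
        ]

    def test_exchange_determinant_history_is_nondecreasing(self):
        rng = np.random.default_rng(0)
        cands = _candidate_set(DesignBounds(), 100, rng)
        Xc, _ = scheffe_matrix(cands, "linear")
        _, history = fedorov_exchange(Xc, 6, rng)
        assert all(b >= a for a, b in zip(history, history[1:]))

    def test_final_design_beats_100_random_subsets(self):
        bounds = DesignBounds()
        seed = 2
        design = doptimal_design(bounds, 6, "linear", seed=seed)
        X, _ = scheffe_matrix(np.array([f.components for f in design]), "linear")
        final_det = np.linalg.det(X.T @ X)
        cands = _candidate_set(bounds, 200, np.random.default_rng(seed))
        Xc, _ = scheffe_matrix(cands, "linear")
        rng = np.random.default_rng(seed + 1)
        for _ in range(100):
            idx = rng.choice(len(Xc), size=6, replace=False)
            assert final_det >= np.linalg.det(Xc[idx].T @ Xc[idx]) - 1e-6

    def test_deterministic_given_seed(self):
        a = doptimal_design(DesignBounds(), 8, "quadratic", seed=5)
        b = doptimal_design(DesignBounds(), 8, "quadratic", seed=5)
        assert [f.components for f in a] == [f.components for f in b]

    def test_too_few_runs_is_rank_error(self):
        with pytest.raises(np.linalg.LinAlgError):
            doptimal_design(DesignBounds(), 2, "linear", seed=0)

    def test_vertices_of_study_bounds_are_in_bounds(self):
        bounds = DesignBounds()
        for v in polytope_vertices(bounds):
            assert bounds.contains(v)
            assert np.isclose(v.sum(), bounds.mixture_total)
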