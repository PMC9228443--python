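"""Response-surface fitting and ANOVA against the measured pilot design.

The coded Box-Behnken columns are orthogonal for linear and interaction
terms, so each such coefficient has the closed form
(mean at +1 − mean at −1) / 2 — used as an independent oracle throughout.
"""

import numpy as np
import pytest

from fructanuf import ResponseSurfaceRegressor, anova, fit_rsm

REDUCED = ("x1:x2", "x2:x3")


def orthogonal_contrast(design, response, col):
    """Closed-form linear coefficient: half the +1/-1 response-mean gap."""
    coded = design.coded[:, col]
    y = design.response(response)
    return (y[coded == 1].mean() - y[coded == -1].mean()) / 2.0


class TestLinearFit:
    def test_ji_coefficients_match_orthogonal_closed_form(self, design):
        fit = fit_rsm(design, "ji", form="linear")
        for i, term in enumerate(["x1", "x2", "x3"]):
            assert fit.coef_coded_[term] == pytest.approx(
                orthogonal_contrast(design, "ji", i), abs=1e-10)
        assert fit.coef_coded_["const"] == pytest.approx(
            design.response("ji").mean(), abs=1e-10)

    def test_ji_published_coefficients(self, design):
        fit = fit_rsm(design, "ji", form="linear")
        assert fit.coef_coded_["const"] == pytest.approx(1.16, abs=5e-3)
        assert fit.coef_coded_["x1"] == pytest.approx(0.3938, abs=5.1e-5)
        assert fit.coef_coded_["x2"] == pytest.approx(0.5238, abs=5.1e-5)
        assert fit.coef_coded_["x3"] == pytest.approx(0.3625, abs=5.1e-5)

    def test_center_prediction_equals_response_mean(self, design):
        fit = fit_rsm(design, "ji", form="linear")
        assert fit.predict_coded([0.0, 0.0, 0.0])[0] == pytest.approx(
            design.response("ji").mean(), abs=1e-12)


class TestQuadraticFit:
    def test_reduced_sf_actual_coefficients_match_published_surface(self, design):
        fit = fit_rsm(design, "sf", form="quadratic_reduced", drop_terms=REDUCED)
        a = fit.coef_actual_
        assert a["const"] == pytest.approx(-1.53, abs=0.01)
        assert a["T"] == pytest.approx(0.129117, abs=1e-4)
        assert a["P"] == pytest.approx(0.630625, abs=1e-6)
        assert a["C"] == pytest.approx(0.005425, abs=1e-6)
        assert a["T:C"] == pytest.approx(0.0001633, abs=1e-6)
        assert a["T^2"] == pytest.approx(-0.001533, abs=1e-5)
        assert a["P^2"] == pytest.approx(-0.095625, abs=1e-6)
        assert a["C^2"] == pytest.approx(-0.000077, abs=1e-6)
        assert a["T:P"] == 0.0 and a["P:C"] == 0.0

    @pytest.mark.parametrize("conditions,expected", [
        ((45, 3, 100), 2.71),
        ((30, 5, 50), 2.05),
        ((54, 4, 120), 2.56),
    ])
    def test_predictions_at_validation_conditions(self, design, conditions, expected):
        fit = fit_rsm(design, "sf", form="quadratic_reduced", drop_terms=REDUCED)
        assert fit.predict([conditions])[0] == pytest.approx(expected, abs=0.02)

    def test_coded_and_actual_views_agree(self, design):
        """predict is invariant under coded<->actual re-expression."""
        fit = fit_rsm(design, "sf", form="quadratic_reduced", drop_terms=REDUCED)
        rng = np.random.default_rng(0)
        pts = np.column_stack([
            rng.uniform(30, 60, 20), rng.uniform(1, 5, 20), rng.uniform(50, 150, 20)])
        via_actual = fit.predict(pts)
        a = fit.coef_actual_
        T, P, C = pts.T
        direct = (a["const"] + a["T"] * T + a["P"] * P + a["C"] * C
                  + a["T:P"] * T * P + a["T:C"] * T * C + a["P:C"] * P * C
                  + a["T^2"] * T ** 2 + a["P^2"] * P ** 2 + a["C^2"] * C ** 2)
        np.testing.assert_allclose(via_actual, direct, atol=1e-9)

    def test_reduced_model_refits_rather_than_zeroing(self, design):
        full = fit_rsm(design, "sf", form="quadratic")
        red = fit_rsm(design, "sf", form="quadratic_reduced", drop_terms=REDUCED)
        assert "x1:x2" not in red.coef_coded_
        # orthogonality: shared coefficients agree, residual df grows by 2
        assert red.coef_coded_["x1"] == pytest.approx(full.coef_coded_["x1"], abs=1e-10)
        assert red.df_resid_ == full.df_resid_ + 2

    def test_constant_response_flags_r2(self, design):
        model = ResponseSurfaceRegressor(form="linear", levels=design.levels)
        model.fit(design.actual, np.full(len(design), 2.0))
        assert np.all(np.abs(model.coef_[1:]) < 1e-12)
        assert np.isnan(model.r2_)

    def test_rank_deficiency_surfaces(self, design):
        model = ResponseSurfaceRegressor(form="quadratic", levels=design.levels)
        X = np.tile(design.actual[:1], (16, 1))  # one repeated point
        with pytest.raises((np.linalg.LinAlgError, ValueError)):
            model.fit(X, design.response("sf"))


class TestAnova:
    def test_sf_full_quadratic_matches_published_table(self, design):
        table = anova(design, "sf", form="quadratic").set_index("term")
        assert table.loc["Pure error", "ss"] == pytest.approx(0.0212, abs=1e-4)
        assert table.loc["Pure error", "df"] == 3
        assert table.loc["x1", "ss"] == pytest.approx(0.1013, abs=5e-4)
        assert table.loc["x2^2", "ss"] == pytest.approx(0.5852, abs=5e-4)
        assert table.loc["x1:x3", "ss"] == pytest.approx(0.0600, abs=5e-4)
        assert table.loc["Total", "df"] == 15
        assert 100 * table.attrs["r2"] == pytest.approx(97.82, abs=0.05)
        assert 100 * table.attrs["r2_adj"] == pytest.approx(94.57, abs=0.05)

    def test_pure_error_from_center_replicates_oracle(self, design):
        """Pure error must equal the center-run scatter computed directly."""
        y = design.response("sf")[design.center_mask()]
        expected = float(np.sum((y - y.mean()) ** 2))
        table = anova(design, "sf", form="quadratic").set_index("term")
        assert table.loc["Pure error", "ss"] == pytest.approx(expected, abs=1e-12)

    def test_ss_decomposition_is_exact(self, design):
        table = anova(design, "sf", form="quadratic").set_index("term")
        assert table.loc["Lack of Fit", "ss"] + table.loc["Pure error", "ss"] == \
            pytest.approx(table.loc["Residual", "ss"], abs=1e-9)

    def test_partial_ss_equals_orthogonal_oracle_for_linear_terms(self, design):
        """For orthogonal coded columns, SS = 8 * ((mean+ - mean-)/2)^2."""
        table = anova(design, "sf", form="quadratic").set_index("term")
        for i, term in enumerate(["x1", "x2", "x3"]):
            beta = orthogonal_contrast(design, "sf", i)
            assert table.loc[term, "ss"] == pytest.approx(8 * beta ** 2, abs=1e-10)

    def test_ji_linear_table(self, design):
        table = anova(design, "ji", form="linear").set_index("term")
        assert table.loc["x2", "ss"] == pytest.approx(2.19, abs=5e-3)
        assert table.loc["Total", "ss"] == pytest.approx(5.98, abs=5e-3)
        assert 100 * table.attrs["r2"] == pytest.approx(75.01, abs=0.05)

    def test_r2_consistent_with_ss_ratio(self, design):
        table = anova(design, "sf", form="quadratic").set_index("term")
        expected = 1 - table.loc["Residual", "ss"] / table.loc["Total", "ss"]
        assert table.attrs["r2"] == pytest.approx(expected, abs=1e-12)

    def test_no_center_replicates_warns_and_omits_pure_error(self, design):
        trimmed = design.frame[~design.center_mask()].iloc[:11]
        from fructanuf.design import DesignTable

        sub = DesignTable(trimmed, design.levels)
        with pytest.warns(UserWarning, match="center replicates"):
            table = anova(sub, "sf", form="linear")
        assert "Pure error" not in set(table["term"])
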