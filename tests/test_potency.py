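"""Potency models, optimal width, HC50 and rat-potency links, OLS refits."""

import numpy as np
import pytest

from empdcc.fixtures import dataset_table, hc50_table, mineral_table, rat_potency_table, testing_sets as reference_testing_sets
from empdcc.metrics import DCCParams, DomainError
from empdcc.potency import (
    hc50_from_dcc,
    optimal_width,
    potency_dcc,
    potency_empa,
    rat_relative_potency,
    refit_regression,
)


class TestPotencyEmpa:
    @pytest.mark.parametrize(
        "empa_pct, expected",
        [(64.8, 0.701), (0.0, -0.012), (30.6, 0.325)],
    )
    def test_reference_values(self, empa_pct, expected):
        assert potency_empa(empa_pct) == pytest.approx(expected, abs=5e-4)

    def test_out_of_range(self):
        with pytest.raises(DomainError):
            potency_empa(120.0)


class TestPotencyDcc:
    @pytest.mark.parametrize(
        "dcc_val, bio, expected, tol",
        [
            (0.11, 66.0, 1.18, 5e-3),  # crocidolite, exact at printed precision
            (0.138, 49.0, 1.362, 0.02),
            (0.082, 181.0, 2.1, 0.15),
        ],
    )
    def test_reference_values(self, dcc_val, bio, expected, tol):
        assert potency_dcc(dcc_val, bio) == pytest.approx(expected, abs=tol)

    def test_vanishes_with_dcc(self):
        assert potency_dcc(1e-9, 66.0) < 1e-10

    def test_monotone_in_both_arguments(self):
        d = np.linspace(0.01, 0.5, 20)
        assert np.all(np.diff(potency_dcc(d, 50.0)) > 0)
        b = np.linspace(1, 300, 20)
        assert np.all(np.diff(potency_dcc(0.05, b)) > 0)

    def test_domain(self):
        with pytest.raises(DomainError):
            potency_dcc(0.0, 66.0)
        with pytest.raises(DomainError):
            potency_dcc(0.05, 0.0)

    def test_mineral_table_reproduction(self):
        """Modelled R_M from printed mean DCC and biosolubility, per mineral."""
        for _, row in mineral_table().iterrows():
            rm = potency_dcc(row["avg_dcc"], row["biosolubility_y"])
            expected = row["rm_modelled"]
            digits = len(str(expected).split(".")[1])
            tol = (0.5 if row["mineral"] == "crocidolite" else 1.5) * 10.0**-digits
            assert rm == pytest.approx(expected, abs=tol), row["mineral"]

    def test_ranking_agreement_with_empa_model(self):
        from scipy.stats import spearmanr

        df = dataset_table()
        rho = spearmanr(df["rm_empa"], df["rm_dcc"]).statistic
        assert rho >= 0.9


class TestOptimalWidth:
    def test_fitted_parameters_give_printed_width(self):
        w = optimal_width()
        assert w == pytest.approx(0.126, abs=5e-4)
        assert 0.1 <= w <= 0.2

    def test_closed_form_matches_numeric_maximum(self):
        from scipy.optimize import minimize_scalar

        p = DCCParams(A=0.11, K=1, B=1000, T=3, C=2)
        w = optimal_width(p)
        assert w == pytest.approx(0.004 ** (1 / 3), rel=1e-9)
        res = minimize_scalar(
            lambda x: -p.A * (np.pi * x**2) ** p.K / (p.B * x**p.T + p.C),
            bounds=(1e-3, 2.0), method="bounded",
        )
        assert res.x == pytest.approx(w, abs=1e-4)

    def test_no_interior_maximum_when_t_le_2k(self):
        with pytest.raises(DomainError):
            optimal_width(DCCParams(T=2.0, K=1.0))


class TestHc50:
    def test_intercept_and_monotonicity(self):
        assert hc50_from_dcc(0.0) == pytest.approx(10**-1.06, rel=1e-9)
        assert hc50_from_dcc(0.01) < hc50_from_dcc(0.05)

    def test_metsovo_model_vs_observed(self):
        # model value for the highest-DCC set; observed is 1.7
        assert hc50_from_dcc(0.068) == pytest.approx(1.27, abs=0.02)


class TestRatPotency:
    @pytest.mark.parametrize(
        "rm, expected",
        [(0.059, 0.67), (0.161, 0.88), (0.748, 1.20), (0.062, 0.68)],
    )
    def test_reference_values(self, rm, expected):
        assert round(rat_relative_potency(rm), 2) == pytest.approx(expected)

    def test_table_reproduction(self):
        rat = rat_potency_table().set_index("mineral")
        for mineral in ("crocidolite", "amosite", "tremolite", "anthophyllite"):
            row = rat.loc[mineral]
            assert round(rat_relative_potency(row["rm_modelled"]), 2) == pytest.approx(
                row["rat_potency_modelled"]
            )

    def test_domain(self):
        with pytest.raises(DomainError):
            rat_relative_potency(0.0)


class TestRefitRegression:
    def test_perfect_line_recovered(self):
        x = np.array([1, 2, 3, 4, 5.0])
        fit = refit_regression(x, 2 * x + 1)
        assert fit.coefficients == pytest.approx((1.0, 2.0))
        assert fit.r == pytest.approx(1.0)

    def test_criteria_fraction_regression(self):
        t = reference_testing_sets()
        fit = refit_regression(t["criteria_fraction"], t["avg_dcc"])
        assert fit.coefficients[1] == pytest.approx(0.06, abs=0.01)
        assert fit.r == pytest.approx(0.96, abs=0.02)
        assert fit.p_value < 1e-5

    def test_pearson_index_regression_signed_negative(self):
        t = reference_testing_sets()
        fit = refit_regression(t["pearson_index"], t["avg_dcc"])
        assert fit.coefficients[1] == pytest.approx(-0.087, abs=0.01)
        assert fit.r == pytest.approx(-0.82, abs=0.02)

    def test_shuffled_predictor_has_no_correlation(self):
        rng = np.random.default_rng(0)
        x = np.arange(200.0)
        fit = refit_regression(x, rng.permutation(x))
        assert abs(fit.r) < 0.15

    def test_r_squared_consistency(self):
        t = reference_testing_sets()
        fit = refit_regression(t["criteria_fraction"], t["avg_dcc"])
        assert fit.r_squared == pytest.approx(fit.r**2)
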