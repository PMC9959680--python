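"""OLS fitting and the regression-diagnostics suite.

Hand-computed oracle values for the 4-point line example
(0,0),(1,1),(2,2),(3,5): slope 1.6, intercept -0.4, RSS 1.2, TSS 14,
ESS 12.8, F = (12.8/1)/(1.2/2) = 21.333..., RMSE = sqrt(1.2/4).
"""

import numpy as np
import pytest
from sklearn.linear_model import LinearRegression

from radqsar import (
    LinearQsarRegressor,
    f_critical,
    f_statistic,
    fit_ols,
    loo_press,
    pearson_matrix,
    predict_linear,
    r2_cv,
    r_squared,
    rmse,
    sum_of_squares,
)
from radqsar.data import ActivityTable, DataSet, DescriptorTable
from radqsar.errors import (
    AlignmentError,
    DegreesOfFreedomError,
    SingularityError,
)
from radqsar.screen import published_equations

LINE_X = np.array([[0.0], [1.0], [2.0], [3.0]])
LINE_Y = np.array([0.0, 1.0, 2.0, 5.0])


class TestFitOls:
    def test_exact_line_recovered(self):
        X = np.array([[0.0], [1.0], [2.0], [3.0]])
        est = LinearQsarRegressor().fit(X, 2 * X.ravel() + 1)
        assert est.coef_[0] == pytest.approx(2.0)
        assert est.intercept_ == pytest.approx(1.0)
        assert est.stats_.r2 == pytest.approx(1.0)

    def test_line_example_normal_equations(self):
        est = LinearQsarRegressor().fit(LINE_X, LINE_Y)
        assert est.coef_[0] == pytest.approx(1.6)
        assert est.intercept_ == pytest.approx(-0.4)

    def test_duplicate_column_names_collinear(self):
        X = np.column_stack([LINE_X, LINE_X])
        with pytest.raises(SingularityError, match="collinear"):
            LinearQsarRegressor().fit(X, LINE_Y)

    def test_matches_sklearn_reference(self, rng):
        X = rng.normal(size=(30, 4))
        y = X @ [1.0, -2.0, 0.5, 3.0] + rng.normal(0, 0.1, 30)
        ours = LinearQsarRegressor().fit(X, y)
        ref = LinearRegression().fit(X, y)
        np.testing.assert_allclose(ours.coef_, ref.coef_, rtol=1e-8)
        assert ours.intercept_ == pytest.approx(ref.intercept_, rel=1e-8)

    def test_insufficient_observations(self):
        with pytest.raises(DegreesOfFreedomError):
            LinearQsarRegressor().fit(np.eye(3), np.ones(3))


class TestPredictLinear:
    def test_zero_inputs_return_intercept(self):
        eq1 = published_equations()["Y1"]
        assert predict_linear(eq1, [[0.0, 0.0, 0.0]])[0] == pytest.approx(
            207.384)

    def test_hydroxyl_equation_arithmetic(self):
        eq1 = published_equations()["Y1"]
        # 207.384 - 90.879*1.5 - 47.988*1.5 + 0.016*100
        assert predict_linear(eq1, [[1.5, 1.5, 100.0]])[0] == pytest.approx(
            0.6835, abs=1e-4)

    def test_superoxide_equation_arithmetic(self):
        eq2 = published_equations()["Y2"]
        # 47.527 - 43.836*1.5 + 0.005*100 - 75.277*(-0.30)
        assert predict_linear(eq2, [[1.5, 100.0, -0.30]])[0] == pytest.approx(
            4.8561, abs=1e-4)

    def test_missing_column_is_alignment_error(self):
        import pandas as pd

        eq1 = published_equations()["Y1"]
        frame = pd.DataFrame({"X17": [1.5], "X19": [1.5]})
        with pytest.raises(AlignmentError, match="X20"):
            predict_linear(eq1, frame)


class TestSumsOfSquares:
    def test_perfect_fit(self):
        rss, tss, ess = sum_of_squares(LINE_Y, LINE_Y)
        assert rss == 0.0
        assert ess == pytest.approx(tss)

    def test_line_example_hand_sums(self):
        yhat = LinearQsarRegressor().fit(LINE_X, LINE_Y).predict(LINE_X)
        rss, tss, ess = sum_of_squares(LINE_Y, yhat)
        assert rss == pytest.approx(1.2)
        assert tss == pytest.approx(14.0)
        assert ess == pytest.approx(12.8)

    def test_constant_prediction_has_zero_ess(self):
        yhat = np.full(4, LINE_Y.mean())
        _, _, ess = sum_of_squares(LINE_Y, yhat)
        assert ess == pytest.approx(0.0)


class TestRSquaredAndF:
    def test_r2_of_line_example(self):
        assert r_squared(12.8, 14.0) == pytest.approx(0.914286, abs=1e-6)

    def test_f_of_line_example(self):
        assert f_statistic(1.2, 12.8, n=4, p=2) == pytest.approx(21.3333,
                                                                 abs=1e-3)

    def test_perfect_fit_overflows_with_warning(self):
        with pytest.warns(UserWarning, match="perfect fit"):
            assert f_statistic(0.0, 14.0, n=4, p=2) == np.inf

    def test_mean_prediction_scores_zero(self):
        assert f_statistic(14.0, 0.0, n=4, p=2) == 0.0

    def test_f_critical_quantiles(self):
        assert f_critical(p=2, n=4) == pytest.approx(18.513, abs=1e-3)
        assert f_critical(p=4, n=12) == pytest.approx(4.066, abs=1e-3)

    def test_f_critical_monotone_in_alpha(self):
        assert f_critical(2, 10, alpha=0.5) < f_critical(2, 10, alpha=0.05)

    def test_f_invariant_to_column_rescaling(self, rng):
        X = rng.normal(size=(20, 3))
        y = X @ [1.0, 2.0, -1.0] + rng.normal(0, 0.5, 20)
        st1 = LinearQsarRegressor().fit(X, y).stats_
        X2 = X.copy()
        X2[:, 1] = 1000.0 * X2[:, 1] + 7.0
        st2 = LinearQsarRegressor().fit(X2, y).stats_
        assert st1.f == pytest.approx(st2.f, rel=1e-9)


class TestPressAndCv:
    def test_exact_line_three_points_gives_zero(self):
        X = np.array([[0.0], [1.0], [2.0]])
        assert loo_press(X, 2 * X.ravel() + 1) == pytest.approx(0.0, abs=1e-18)

    def test_matches_hat_matrix_closed_form(self, rng):
        """Refit-loop PRESS equals sum((e_i / (1 - h_ii))^2) for OLS."""
        for _ in range(5):
            X = rng.normal(size=(15, 3))
            y = X @ [1.0, -1.0, 0.5] + rng.normal(0, 0.4, 15)
            D = np.column_stack([np.ones(15), X])
            H = D @ np.linalg.inv(D.T @ D) @ D.T
            e = y - H @ y
            closed = np.sum((e / (1 - np.diag(H))) ** 2)
            assert loo_press(X, y) == pytest.approx(closed, rel=1e-8)

    def test_press_at_least_rss(self, rng):
        X = rng.normal(size=(12, 2))
        y = rng.normal(size=12)
        est = LinearQsarRegressor().fit(X, y)
        assert est.stats_.press >= est.stats_.rss

    def test_r2cv_limits(self):
        assert r2_cv(0.0, 14.0) == 1.0
        assert r2_cv(14.0, 14.0) == 0.0
        assert r2_cv(20.0, 14.0) < 0  # hopeless models go negative

    def test_line_example_r2cv_from_brute_force(self):
        press = loo_press(LINE_X, LINE_Y)
        assert r2_cv(press, 14.0) == pytest.approx(1 - press / 14.0)


class TestRmse:
    def test_hand_arithmetic(self):
        y = np.zeros(4)
        yhat = np.array([0.4, -0.2, -0.8, 0.6])
        assert rmse(y, yhat) == pytest.approx(np.sqrt(1.2 / 4), abs=1e-4)

    def test_constant_offset(self):
        y = np.arange(5.0)
        assert rmse(y, y + 0.7) == pytest.approx(0.7)


class TestOlsInvariants:
    """Decomposition identities hold on every OLS-with-intercept fit."""

    @pytest.mark.parametrize("seed", range(5))
    def test_tss_decomposition_and_r2_agreement(self, seed):
        rng = np.random.default_rng(seed)
        n, k = rng.integers(8, 40), rng.integers(1, 5)
        X = rng.normal(size=(n, k))
        y = X @ rng.normal(size=k) + rng.normal(0, 0.5, n)
        est = LinearQsarRegressor().fit(X, y)
        st = est.stats_
        assert st.tss == pytest.approx(st.ess + st.rss, rel=1e-9)
        assert st.r2 == pytest.approx(1 - st.rss / st.tss, rel=1e-9)
        assert 0.0 <= st.r2 <= 1.0

    def test_parameter_recovery_within_3_se(self):
        rng = np.random.default_rng(7)
        beta = np.array([2.0, -1.5, 0.7])
        X = rng.normal(size=(200, 3))
        y = 1.0 + X @ beta + rng.normal(0, 0.2, 200)
        est = LinearQsarRegressor().fit(X, y)
        D = np.column_stack([np.ones(200), X])
        cov = est.stats_.rss / (200 - 4) * np.linalg.inv(D.T @ D)
        se = np.sqrt(np.diag(cov))
        full = np.concatenate([[1.0], beta])
        fitted = np.concatenate([[est.intercept_], est.coef_])
        assert np.all(np.abs(fitted - full) <= 3 * se)


class TestPearsonMatrix:
    def _ds(self, values):
        n = len(values)
        ids = [f"c{i}" for i in range(n)]
        y1 = np.asarray(values, float)[:, 0]
        y1 = (y1 - y1.min()) / (np.ptp(y1) + 1e-9) * 9
        return DataSet(DescriptorTable(ids, np.asarray(values, float)),
                       ActivityTable(ids, y1, 9 - y1, y1 / 2))

    def test_diagonal_and_negation(self, rng):
        values = rng.normal(size=(8, 2))
        ds = self._ds(values)
        corr = pearson_matrix(ds)
        assert np.allclose(np.diag(corr), 1.0)
        assert corr.loc["Y1", "Y2"] == pytest.approx(-1.0)  # Y2 = 9 - Y1
        assert ((corr.abs() <= 1 + 1e-12) | corr.isna()).all().all()

    def test_matches_textbook_formula(self):
        a = np.array([1.0, 2.0, 4.0, 5.0, 9.0])
        b = np.array([2.0, 1.0, 5.0, 4.0, 8.0])
        ds = self._ds(np.column_stack([a, b]))
        expected = (((a - a.mean()) * (b - b.mean())).sum()
                    / np.sqrt(((a - a.mean()) ** 2).sum()
                              * ((b - b.mean()) ** 2).sum()))
        assert ds and pearson_matrix(ds).loc["X1", "X2"] == pytest.approx(
            expected, rel=1e-12)

    def test_zero_variance_column_flagged_undefined(self, rng):
        values = np.column_stack([rng.normal(size=6), np.full(6, 3.0)])
        ds = self._ds(values)
        with pytest.warns(UserWarning, match="zero-variance"):
            corr = pearson_matrix(ds)
        assert np.isnan(corr.loc["X2", "X1"])
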