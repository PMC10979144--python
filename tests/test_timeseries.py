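import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pmhia.errors import CollinearityError, EmptyInputError
from pmhia.exposure import DailySeries
from pmhia.timeseries import build_design, coefficient_table, fit_ols


def daily(values, start="2019-01-01", name="x"):
    values = np.asarray(values, dtype=float)
    dates = pd.date_range(start, periods=len(values), freq="D")
    return DailySeries(dates, values, np.full(len(values), 24), name)


class TestBuildDesign:
    def test_two_month_span_has_one_indicator(self):
        # 59 days: 1 Jan – 28 Feb
        design = build_design(daily(np.arange(59.0) + 5), reference_month="January")
        assert design.month_columns == ["February"]
        assert design.reference_month == "January"
        assert list(design.X.columns) == ["const", "trend", "February"]

    def test_all_dates_in_reference_month_no_indicators(self):
        design = build_design(daily(np.ones(20) * 8))
        assert design.month_columns == []
        assert design.reference_month == "January"

    def test_trend_is_zero_based_day_index(self):
        design = build_design(daily(np.ones(10)))
        np.testing.assert_array_equal(design.X["trend"], np.arange(10.0))

    def test_gapped_covariates_match_date_intersection_oracle(self):
        rng = np.random.default_rng(23)
        pm = daily(rng.uniform(10, 40, 90))
        cov_vals = rng.normal(15, 5, 90)
        keep = rng.random(90) > 0.3
        cov = DailySeries(
            pm.dates[keep], cov_vals[keep], np.full(int(keep.sum()), 24), "temperature"
        )
        design = build_design(pm, {"temperature": cov})
        expected_dates = sorted(set(pm.dates) & set(cov.dates))
        assert list(design.y.index) == expected_dates
        assert design.n_dropped == 90 - len(expected_dates)

    def test_disjoint_dates_rejected(self):
        pm = daily(np.ones(5), start="2019-01-01")
        cov = daily(np.ones(5), start="2020-06-01", name="temperature")
        with pytest.raises(EmptyInputError):
            build_design(pm, {"temperature": cov})


class TestFitOLS:
    def test_constant_response(self):
        design = build_design(daily(np.full(30, 3.0)))
        fit = fit_ols(design)
        assert fit.params["const"] == pytest.approx(3.0, abs=1e-12)
        assert fit.params["trend"] == pytest.approx(0.0, abs=1e-12)
        assert fit.r_squared == 0.0

    def test_exact_line_recovered(self):
        t = np.arange(25.0)
        design = build_design(daily(2.0 * t + 7.0))
        fit = fit_ols(design)
        assert fit.params["trend"] == pytest.approx(2.0, abs=1e-10)
        assert fit.params["const"] == pytest.approx(7.0, abs=1e-10)
        assert np.abs(fit.resid).max() < 1e-9

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(41)
        n = 200
        pm = daily(rng.uniform(5, 60, n))
        met = {
            name: daily(rng.normal(loc, 5, n), name=name)
            for name, loc in [("temperature", 15), ("wind_speed", 30)]
        }
        design = build_design(pm, met)
        fit = fit_ols(design)

        X = design.X.to_numpy(float)
        y = design.y.to_numpy(float)
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        resid = y - X @ beta
        p = X.shape[1]
        sigma2 = resid @ resid / (n - p)
        se = np.sqrt(np.diag(sigma2 * np.linalg.inv(X.T @ X)))
        tvals = beta / se
        pvals = 2 * stats.t.sf(np.abs(tvals), n - p)

        np.testing.assert_allclose(fit.params.to_numpy(), beta, rtol=1e-8)
        np.testing.assert_allclose(fit.bse.to_numpy(), se, rtol=1e-8)
        np.testing.assert_allclose(fit.pvalues.to_numpy(), pvals, rtol=1e-8, atol=1e-12)
        assert fit.sigma2 == pytest.approx(sigma2, rel=1e-10)

    def test_residuals_orthogonal_to_design(self):
        rng = np.random.default_rng(42)
        n = 150
        design = build_design(
            daily(rng.uniform(5, 60, n)),
            {"temperature": daily(rng.normal(15, 8, n), name="temperature")},
        )
        fit = fit_ols(design)
        y_norm = np.linalg.norm(design.y.to_numpy(float))
        for col in design.X.columns:
            x = design.X[col].to_numpy(float)
            assert abs(x @ fit.resid) <= 1e-8 * np.linalg.norm(x) * y_norm

    def test_collinear_design_names_dependent_column(self):
        rng = np.random.default_rng(13)
        n = 40
        base = rng.normal(15, 5, n)
        design = build_design(
            daily(rng.uniform(5, 60, n)),
            {
                "temperature": daily(base, name="temperature"),
                "temp_copy": daily(2.0 * base, name="temp_copy"),
            },
        )
        with pytest.raises(CollinearityError, match="temp"):
            fit_ols(design)


class TestCoefficientTable:
    def test_row_order_and_rounding(self):
        rng = np.random.default_rng(8)
        n = 120
        design = build_design(
            daily(rng.uniform(5, 60, n)),
            {"temperature": daily(rng.normal(15, 6, n), name="temperature")},
        )
        table = coefficient_table(fit_ols(design))
        assert list(table.term[:3]) == ["const", "temperature", "trend"]
        assert set(table.term[3:]) <= {
            "February", "March", "April", "May",
        }
        assert (table.est == table.est.round(2)).all()
        assert (table.p == table.p.round(3)).all()

    def test_strong_trend_reports_p_as_zero(self):
        t = np.arange(200.0)
        rng = np.random.default_rng(2)
        design = build_design(daily(10 + 0.5 * t + rng.normal(0, 1, 200)))
        table = coefficient_table(fit_ols(design)).set_index("term")
        assert table.loc["trend", "p"] == 0.0

    def test_intercept_and_trend_only_without_covariates(self):
        design = build_design(daily(np.arange(20.0) + 3), reference_month="January")
        table = coefficient_table(fit_ols(design))
        assert list(table.term) == ["const", "trend"]

    def test_emit_parse_round_trip(self, tmp_path):
        design = build_design(daily(np.arange(40.0) + 3))
        table = coefficient_table(fit_ols(design))
        path = tmp_path / "table.csv"
        table.to_csv(path, index=False)
        again = pd.read_csv(path)
        pd.testing.assert_frame_equal(table, again)


def test_confidence_interval_covers_exact_fit():
    t = np.arange(50.0)
    design = build_design(daily(1.5 * t + 4.0))
    fit = fit_ols(design)
    ci = fit.conf_int()
    assert ci.loc["trend", "lower"] <= 1.5 <= ci.loc["trend", "upper"]
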