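"""Statistics suite: descriptive, correlation, GoF, regression, ledger."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from peakfit import synthetic
from peakfit.config import Spectrum
from peakfit.exceptions import (DegreesOfFreedomError, InputValidationError,
                                PeakfitError)
from peakfit.model import SpectralModel
from peakfit.statistics import (MetricLedger, correlation_matrix, descriptive,
                                goodness_of_fit, metric_history,
                                regression_metrics, residual_trend, six_tables)
from tests.conftest import gaussian_project


class TestDescriptive:
    def test_constant_vector_zero_sd(self):
        s = Spectrum(x=np.arange(5.0), y=np.full(5, 3.3))
        table = descriptive(s)
        assert table.loc["std", "intensity"] == 0.0

    def test_linear_ramp_summary(self):
        s = Spectrum(x=np.arange(11.0), y=np.arange(11.0))
        t = descriptive(s)
        assert t.loc["min", "intensity"] == 0
        assert t.loc["max", "intensity"] == 10
        assert t.loc["mean", "intensity"] == 5
        assert t.loc["50%", "intensity"] == 5  # interpolated order statistic

    def test_ten_percent_steps_present(self):
        s = Spectrum(x=np.arange(11.0), y=np.arange(11.0))
        rows = set(descriptive(s).index)
        assert {f"{p}%" for p in range(10, 100, 10)} <= rows


class TestCorrelation:
    def test_self_correlation_is_one(self):
        v = np.random.default_rng(0).normal(size=50)
        cm = correlation_matrix({"a": v, "b": 2 * v + 1})
        assert cm.matrix.loc["a", "a"] == 1.0
        assert cm.matrix.loc["a", "b"] == pytest.approx(1.0, abs=1e-12)

    def test_opposite_sign_identical_gaussians_give_minus_one(self):
        from peakfit.lineshapes import eval_peak
        x = np.linspace(-5, 5, 200)
        up = eval_peak("gaussian", x, {"amplitude": 1.0, "fwhmg": 1.0})
        cm = correlation_matrix({"model_1": up, "model_2": -up})
        assert abs(cm.matrix.loc["model_1", "model_2"] - (-1.0)) <= 1e-10

    def test_half_fwhm_shift_correlation_in_unit_interval(self):
        from peakfit.lineshapes import eval_peak
        x = np.linspace(-10, 10, 400)
        a = eval_peak("gaussian", x, {"amplitude": 1.0, "fwhmg": 2.0,
                                      "center": 0.0})
        b = eval_peak("gaussian", x, {"amplitude": 1.0, "fwhmg": 2.0,
                                      "center": 1.0})
        r = correlation_matrix({"a": a, "b": b}).matrix.loc["a", "b"]
        assert 0.0 < r < 1.0

    def test_matches_brute_force_to_1e12(self):
        rng = np.random.default_rng(3)
        series = {k: rng.normal(size=40) for k in "abcd"}
        cm = correlation_matrix(series).matrix
        for i in "abcd":
            for j in "abcd":
                u, v = series[i] - series[i].mean(), series[j] - series[j].mean()
                brute = float(u @ v / np.sqrt((u @ u) * (v @ v)))
                assert cm.loc[i, j] == pytest.approx(brute, abs=1e-12)

    def test_degenerate_series_flagged_not_zero(self):
        cm = correlation_matrix({"a": np.arange(5.0), "flat": np.ones(5)})
        assert math.isnan(cm.matrix.loc["a", "flat"])
        assert ("a", "flat") in cm.undefined

    def test_length_mismatch_is_error(self):
        with pytest.raises(InputValidationError):
            correlation_matrix({"a": np.arange(5.0), "b": np.arange(6.0)})


class TestGoodnessOfFit:
    def test_formula_values(self):
        # N=100, chi2=0.01, k=5 -> aic = 100*ln(1e-4) + 10
        r = np.full(100, 0.01)  # sum r^2 = 0.01
        gof = goodness_of_fit(r, k=5)
        assert gof.chi2 == pytest.approx(0.01, rel=1e-12)
        assert gof.aic == pytest.approx(100 * math.log(1e-4) + 10, rel=1e-12)
        assert gof.aic == pytest.approx(-911.034, abs=5e-4)
        assert gof.bic - gof.aic == pytest.approx(5 * (math.log(100) - 2),
                                                  rel=1e-12)
        assert gof.bic - gof.aic == pytest.approx(13.026, abs=5e-4)

    def test_zero_residual_hits_documented_floor(self):
        gof = goodness_of_fit(np.zeros(50), k=3)
        assert gof.chi2 == 0.0
        assert gof.aic == pytest.approx(50 * math.log(1e-250 / 50) + 6)

    def test_red_chi2_denominator(self):
        gof = goodness_of_fit(np.ones(10), k=4)
        assert gof.red_chi2 == pytest.approx(10 / 6)

    def test_dof_error(self):
        with pytest.raises(DegreesOfFreedomError):
            goodness_of_fit(np.ones(3), k=3)

    @settings(max_examples=20, derandomize=True)
    @given(n=st.integers(10, 200), k=st.integers(0, 8),
           scale=st.floats(1e-6, 10))
    def test_bic_aic_identity(self, n, k, scale):
        r = np.random.default_rng(1).normal(0, scale, n)
        gof = goodness_of_fit(r, k=k)
        assert gof.bic - gof.aic == pytest.approx(k * (math.log(n) - 2),
                                                  rel=1e-12, abs=1e-12)

    def test_chi2_non_increasing_on_nested_ladder(self):
        """More free peaks can only lower the residual sum of squares."""
        truth = [{"amplitude": 1.0, "center": 3.0, "fwhmg": 1.2},
                 {"amplitude": 0.8, "center": 6.0, "fwhmg": 1.2},
                 {"amplitude": 1.2, "center": 8.0, "fwhmg": 1.2}]
        t = synthetic.TruthTable.build(
            [("gaussian", a) for a in truth], noise_sd=0.02, seed=5,
            grid=(0.0, 11.0, 220))
        s, _ = synthetic.make_spectrum(t)
        chi2s = []
        for k in (1, 2, 3):
            project = gaussian_project(truth[:k], lo=0, hi=11)
            res = SpectralModel(project, s).fit()
            chi2s.append(res.gof.chi2)
        assert chi2s[0] >= chi2s[1] >= chi2s[2]


class TestRegressionMetrics:
    def test_perfect_prediction(self):
        y = np.array([1.0, 2.0, 3.0, 2.0])
        m = regression_metrics(y, y)
        assert m.r2 == 1.0 and m.evs == 1.0
        assert m.mae == 0.0 and m.rmse == 0.0

    def test_constant_mean_prediction_r2_zero(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        m = regression_metrics(y, np.full(4, y.mean()))
        assert m.r2 == pytest.approx(0.0, abs=1e-12)

    def test_constant_offset_splits_evs_and_r2(self):
        y = np.random.default_rng(0).normal(size=30)
        m = regression_metrics(y, y + 0.5)
        assert m.evs == pytest.approx(1.0, abs=1e-12)
        assert m.r2 < 1.0

    def test_rmse_is_sqrt_mse(self):
        y = np.arange(10.0)
        m = regression_metrics(y, y + np.sin(y))
        assert m.rmse == pytest.approx(math.sqrt(m.mse), rel=1e-14)

    def test_brute_force_agreement(self):
        rng = np.random.default_rng(9)
        y, yhat = rng.normal(size=60), rng.normal(size=60)
        m = regression_metrics(y, yhat)
        r = y - yhat
        assert m.mae == pytest.approx(np.mean(np.abs(r)), abs=1e-12)
        assert m.mse == pytest.approx(np.mean(r**2), abs=1e-12)
        assert m.r2 == pytest.approx(1 - np.sum(r**2) /
                                     np.sum((y - y.mean())**2), abs=1e-12)
        assert m.evs == pytest.approx(1 - np.var(r) / np.var(y), abs=1e-12)

    def test_zero_variance_flagged(self):
        m = regression_metrics(np.ones(5), np.arange(5.0))
        assert not m.defined and math.isnan(m.r2)

    @settings(max_examples=30, derandomize=True)
    @given(offset=st.floats(-2, 2), noise=st.floats(0, 1))
    def test_evs_never_below_r2(self, offset, noise):
        rng = np.random.default_rng(7)
        y = rng.normal(size=40)
        yhat = y + offset + noise * rng.normal(size=40)
        m = regression_metrics(y, yhat)
        assert m.evs >= m.r2 - 1e-12


class TestResidualTrend:
    def test_zero_residual_zero_line(self):
        t = residual_trend(np.linspace(0, 1, 20), np.zeros(20))
        assert t.slope == 0.0 and t.intercept == 0.0

    def test_exact_line_recovered_zero_band(self):
        x = np.linspace(0, 5, 30)
        t = residual_trend(x, 2 * x + 1)
        assert t.slope == pytest.approx(2.0, rel=1e-12)
        assert t.intercept == pytest.approx(1.0, rel=1e-12)
        assert np.max(t.band_upper - t.band_lower) < 1e-10

    def test_antisymmetric_residual_zero_slope(self):
        x = np.linspace(-3, 3, 61)  # symmetric grid
        t = residual_trend(x, np.sin(np.pi * x) * 0 + x**2 - np.mean(x**2))
        assert abs(t.slope) <= 1e-12

    def test_band_widens_with_lower_confidence_level(self):
        rng = np.random.default_rng(2)
        x = np.linspace(0, 1, 50)
        r = rng.normal(0, 0.1, 50)
        narrow = residual_trend(x, r, conf=0.68)
        wide = residual_trend(x, r, conf=0.99)
        assert (wide.band_upper - wide.band_lower).mean() > \
            (narrow.band_upper - narrow.band_lower).mean()

    def test_constant_x_is_error(self):
        with pytest.raises(InputValidationError):
            residual_trend(np.ones(10), np.arange(10.0))


class TestMetricLedger:
    def _result(self, seed=0):
        t = synthetic.TruthTable.build(
            [("gaussian", {"amplitude": 2.0, "center": 5.0, "fwhmg": 1.5})],
            noise_sd=0.01, seed=seed, grid=(0.0, 10.0, 101))
        s, _ = synthetic.make_spectrum(t)
        project = gaussian_project([{"amplitude": 2.0, "center": 5.0,
                                     "fwhmg": 1.5}])
        return SpectralModel(project, s).fit().results[0]

    def test_thirteen_fit_cycles(self):
        ledger = MetricLedger()
        for seed in range(13):
            metric_history(ledger, self._result(seed))
        assert len(ledger) == 13
        assert list(ledger.to_frame().columns) == ["aic", "bic", "mse"]

    def test_custom_metric_list(self):
        ledger = MetricLedger(metrics=("red_chi2", "mse", "r2"))
        ledger.append(self._result())
        assert set(ledger.records[0]) == {"red_chi2", "mse", "r2"}

    def test_empty_metric_list_is_error(self):
        with pytest.raises(InputValidationError):
            MetricLedger(metrics=())

    def test_unknown_metric_name_lists_valid(self):
        with pytest.raises(InputValidationError, match="aic"):
            MetricLedger(metrics=("nope",))


class TestSixTables:
    def test_order_and_content(self):
        res = TestMetricLedger()._result()
        tables = six_tables(res.spectrum, res)
        assert list(tables) == [
            "Statistics", "Fit Statistics", "Variables and Values",
            "Correlation of Component", "Overall Linear-Correlation",
            "Regression Metrics"]
        overall = tables["Overall Linear-Correlation"]
        assert "energy" in overall.columns and "fit" in overall.columns
        comp = tables["Correlation of Component"]
        assert "energy" not in comp.columns
        assert tables["Overall Linear-Correlation"].loc["intensity", "fit"] \
            == pytest.approx(1.0, abs=1e-3)  # near-perfect fit correlates ~100%
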