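"""Model evaluation, bounded least-squares fitting, uncertainties."""

import json

import numpy as np
import pytest

import lmfit  # independent cross-check backend

from peakfit.config import (ComponentSpec, FitProject, ParameterSpec,
                            Settings, Spectrum, parse_input, preprocess)
from peakfit.exceptions import PeakfitError, UnderdeterminedError
from peakfit.parameters import build_names
from peakfit.solver import confidence_intervals, evaluate_model, fit
from tests.conftest import gaussian_project

GAUSS_HEIGHT = 2 * np.sqrt(np.log(2) / np.pi)  # unit-area, unit-FWHM


class TestEvaluateModel:
    def test_single_gaussian_default_height(self, single_gaussian_project):
        project = gaussian_project([{"amplitude": 1.0, "center": 0.0,
                                     "fwhmg": 1.0}], lo=-5, hi=5)
        ps = build_names(project.components)
        curve, comps = evaluate_model(ps, project.components, np.array([0.0]))
        assert curve[0] == pytest.approx(GAUSS_HEIGHT, rel=1e-12)
        assert list(comps) == ["gaussian_1"]

    def test_sum_of_components_contract(self):
        project = gaussian_project([
            {"amplitude": 1.0, "center": 3.0, "fwhmg": 1.0},
            {"amplitude": 2.0, "center": 6.0, "fwhmg": 2.0}])
        ps = build_names(project.components)
        grid = np.linspace(0, 10, 101)
        curve, comps = evaluate_model(ps, project.components, grid)
        np.testing.assert_allclose(curve, sum(comps.values()), atol=1e-10)

    def test_two_identical_components_double(self):
        one = gaussian_project([{"amplitude": 1.0, "center": 5.0, "fwhmg": 1.5}])
        two = gaussian_project([{"amplitude": 1.0, "center": 5.0, "fwhmg": 1.5}] * 2)
        grid = np.linspace(0, 10, 50)
        c1, _ = evaluate_model(build_names(one.components), one.components, grid)
        c2, _ = evaluate_model(build_names(two.components), two.components, grid)
        np.testing.assert_allclose(c2, 2 * c1, rtol=1e-14)

    def test_zero_amplitude_zero_curve(self):
        project = gaussian_project([{"amplitude": 0.0, "center": 5.0,
                                     "fwhmg": 1.5}])
        curve, _ = evaluate_model(build_names(project.components),
                                  project.components, np.linspace(0, 10, 20))
        np.testing.assert_array_equal(curve, 0.0)


class TestFit:
    def test_noiseless_recovery_within_1e6_relative(self):
        truth = {"amplitude": 2.0, "center": 5.0, "fwhmg": 1.5}
        x = np.linspace(0, 10, 146)
        clean, _ = evaluate_model(
            build_names(gaussian_project([truth]).components),
            gaussian_project([truth]).components, x)
        init = {"amplitude": 2.4, "center": 4.2, "fwhmg": 1.2}  # within 20%
        res = fit(gaussian_project([init]), Spectrum(x=x, y=clean))
        assert res.success
        for attr, tv in truth.items():
            assert res.params[f"gaussian_{attr}_1"].value == pytest.approx(
                tv, rel=1e-6)

    def test_data_at_initial_model_is_noop(self):
        truth = {"amplitude": 2.0, "center": 5.0, "fwhmg": 1.5}
        project = gaussian_project([truth])
        x = np.linspace(0, 10, 101)
        clean, _ = evaluate_model(build_names(project.components),
                                  project.components, x)
        res = fit(project, Spectrum(x=x, y=clean))
        assert np.abs(res.residual).max() < 1e-12
        for attr, tv in truth.items():
            assert res.params[f"gaussian_{attr}_1"].value == pytest.approx(
                tv, rel=1e-8)

    def test_refit_from_optimum_is_noop(self, noisy_gaussian_spectrum):
        spectrum, truth = noisy_gaussian_spectrum
        res1 = fit(gaussian_project([truth]), spectrum)
        best = {n: res1.params[n].value for n in res1.free_names}
        init = [{"amplitude": best["gaussian_amplitude_1"],
                 "center": best["gaussian_center_1"],
                 "fwhmg": best["gaussian_fwhmg_1"]}]
        res2 = fit(gaussian_project(init), spectrum)
        for n, v in best.items():
            assert res2.params[n].value == pytest.approx(v, rel=1e-8)

    def test_rss_not_worse_than_initialization(self, noisy_gaussian_spectrum):
        spectrum, truth = noisy_gaussian_spectrum
        init = {"amplitude": 2.4, "center": 4.5, "fwhmg": 1.8}
        project = gaussian_project([init])
        ps = build_names(project.components)
        model0, _ = evaluate_model(ps, project.components, spectrum.x)
        rss0 = np.sum((spectrum.y - model0) ** 2)
        res = fit(project, spectrum)
        assert res.gof.chi2 <= rss0

    def test_bounds_respected(self, noisy_gaussian_spectrum):
        spectrum, _ = noisy_gaussian_spectrum
        comps = [ComponentSpec(index="1", kind="gaussian", attributes={
            "amplitude": ParameterSpec(value=1.0, min=0.0, max=1.5),
            "center": ParameterSpec(value=4.0, min=3.0, max=4.5),
            "fwhmg": ParameterSpec(value=1.0, min=0.5, max=4.0)})]
        res = fit(FitProject(components=comps), spectrum)
        for p in res.params:
            assert p.min <= p.value <= p.max

    def test_stderr_is_sqrt_diag_covariance(self, noisy_gaussian_spectrum):
        spectrum, truth = noisy_gaussian_spectrum
        res = fit(gaussian_project([truth]), spectrum)
        assert res.covariance is not None
        for i, n in enumerate(res.free_names):
            assert res.params[n].stderr == pytest.approx(
                np.sqrt(res.covariance[i, i]), rel=1e-10)

    def test_covariance_symmetric_psd(self, noisy_gaussian_spectrum):
        spectrum, truth = noisy_gaussian_spectrum
        res = fit(gaussian_project([truth]), spectrum)
        cov = res.covariance
        np.testing.assert_allclose(cov, cov.T, atol=1e-18)
        assert (np.linalg.eigvalsh(cov) > -1e-18).all()

    def test_abscissa_shift_invariance(self, noisy_gaussian_spectrum):
        spectrum, truth = noisy_gaussian_spectrum
        res0 = fit(gaussian_project([truth]), spectrum)
        shifted = preprocess(spectrum, shift=100.0)
        init = dict(truth)
        init["center"] += 100.0
        res1 = fit(gaussian_project([init], lo=100, hi=110), shifted)
        assert res1.params["gaussian_center_1"].value == pytest.approx(
            res0.params["gaussian_center_1"].value + 100.0, rel=1e-9)
        for attr in ("amplitude", "fwhmg"):
            assert res1.params[f"gaussian_{attr}_1"].value == pytest.approx(
                res0.params[f"gaussian_{attr}_1"].value, rel=1e-6)

    def test_underdetermined_is_error(self):
        project = gaussian_project([{"amplitude": 1.0, "center": 1.0,
                                     "fwhmg": 1.0}])
        s = Spectrum(x=np.array([0.0, 1.0, 2.0]),
                     y=np.array([0.1, 0.5, 0.1]))
        with pytest.raises(UnderdeterminedError):
            fit(project, s)

    def test_method_kwargs_forwarded(self, noisy_gaussian_spectrum):
        spectrum, truth = noisy_gaussian_spectrum
        res = fit(gaussian_project([truth]), spectrum,
                  method_kwargs={"max_nfev": 3})
        assert res.n_eval <= 4  # optimizer honored the forwarded cap

    def test_non_lsq_method_runs_without_covariance(
            self, noisy_gaussian_spectrum):
        spectrum, truth = noisy_gaussian_spectrum
        res = fit(gaussian_project([truth]), spectrum, method="Nelder-Mead",
                  method_kwargs={"options": {"maxiter": 2000}})
        assert res.covariance is None
        assert all(res.params[n].stderr is None for n in res.free_names)

    def test_matches_lmfit_reference(self, noisy_gaussian_spectrum):
        """Independent oracle: the same Gaussian fit through lmfit's
        area-parameterized GaussianModel must land on the same optimum."""
        spectrum, truth = noisy_gaussian_spectrum
        res = fit(gaussian_project([truth]), spectrum)
        sigma = truth["fwhmg"] / (2 * np.sqrt(2 * np.log(2)))
        gm = lmfit.models.GaussianModel()
        ref = gm.fit(spectrum.y, x=spectrum.x,
                     amplitude=truth["amplitude"], center=truth["center"],
                     sigma=sigma)
        assert res.params["gaussian_amplitude_1"].value == pytest.approx(
            ref.params["amplitude"].value, rel=1e-6)
        assert res.params["gaussian_center_1"].value == pytest.approx(
            ref.params["center"].value, rel=1e-8)
        assert res.params["gaussian_fwhmg_1"].value == pytest.approx(
            ref.params["fwhm"].value, rel=1e-6)
        assert res.params["gaussian_center_1"].stderr == pytest.approx(
            ref.params["center"].stderr, rel=1e-3)

    def test_center_coverage_three_overlapping_gaussians(self):
        """True centers inside +-3*stderr in >=90% of 50 noisy replicas."""
        truths = [{"amplitude": 1.0, "center": 3.5, "fwhmg": 1.2},
                  {"amplitude": 0.8, "center": 5.0, "fwhmg": 1.2},
                  {"amplitude": 1.1, "center": 6.5, "fwhmg": 1.2}]
        project = gaussian_project(truths)
        ps = build_names(project.components)
        x = np.linspace(0, 10, 201)
        clean, _ = evaluate_model(ps, project.components, x)
        hits = 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            s = Spectrum(x=x, y=clean + rng.normal(0, 0.005, x.size))
            res = fit(gaussian_project(truths), s)
            ok = all(
                abs(res.params[f"gaussian_center_{i}"].value - t["center"])
                <= 3 * res.params[f"gaussian_center_{i}"].stderr
                for i, t in enumerate(truths, start=1))
            hits += ok
        assert hits >= 45


class TestConfidenceIntervals:
    def _linear_fit(self, noise_sd=0.05, n=80, slope=2.0):
        rng = np.random.default_rng(4)
        x = np.linspace(0.5, 8, n)
        y = slope * x + rng.normal(0, noise_sd, n)
        comps = [ComponentSpec(index="1", kind="linear", attributes={
            "slope": ParameterSpec(value=1.5),
            "intercept": ParameterSpec(value=0.0, vary=False)})]
        project = FitProject(components=comps)
        return project, fit(project, Spectrum(x=x, y=y))

    def test_one_sigma_matches_closed_form_stderr(self):
        project, res = self._linear_fit()
        report = confidence_intervals(project, res, sigmas=(1,))
        ci = report.intervals["linear_slope_1"][0]
        best = res.params["linear_slope_1"].value
        se = res.params["linear_slope_1"].stderr
        half = (ci.upper - ci.lower) / 2
        assert half == pytest.approx(se, rel=0.15)
        assert ci.lower < best < ci.upper

    def test_intervals_nested_and_contain_best(self, noisy_gaussian_spectrum):
        spectrum, truth = noisy_gaussian_spectrum
        project = gaussian_project([truth])
        res = fit(project, spectrum)
        report = confidence_intervals(project, res, sigmas=(1, 2))
        for cis in report.intervals.values():
            one, two = cis
            assert two.lower <= one.lower and one.upper <= two.upper

    def test_symmetric_problem_gives_symmetric_interval(self):
        project, res = self._linear_fit()
        ci = confidence_intervals(project, res, sigmas=(1,)).intervals[
            "linear_slope_1"][0]
        best = res.params["linear_slope_1"].value
        half = (ci.upper - ci.lower) / 2
        asym = abs((ci.upper - best) - (best - ci.lower))
        assert asym < 0.1 * half

    def test_parameter_at_bound_flags_one_side(self, noisy_gaussian_spectrum):
        spectrum, truth = noisy_gaussian_spectrum
        comps = [ComponentSpec(index="1", kind="gaussian", attributes={
            # bound sits at the best value: upward profiling cannot bracket
            "amplitude": ParameterSpec(value=1.0, min=0.0, max=1.0),
            "center": ParameterSpec(value=5.0, min=0.0, max=10.0),
            "fwhmg": ParameterSpec(value=1.5, min=0.1, max=10.0)})]
        project = FitProject(components=comps)
        res = fit(project, spectrum)
        assert res.params["gaussian_amplitude_1"].value == pytest.approx(1.0)
        report = confidence_intervals(project, res, sigmas=(1,))
        ci = report.intervals["gaussian_amplitude_1"][0]
        assert ci.upper is None and ci.lower is not None

    def test_requires_converged_fit(self, noisy_gaussian_spectrum):
        spectrum, truth = noisy_gaussian_spectrum
        res = fit(gaussian_project([truth]), spectrum)
        res.success = False
        with pytest.raises(PeakfitError):
            confidence_intervals(gaussian_project([truth]), res)
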