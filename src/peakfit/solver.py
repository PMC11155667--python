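"""Composite-model assembly and bounded nonlinear least squares.

The model for one spectrum is the elementwise sum of its components
(peaks, steps, backgrounds) evaluated from a resolved
:class:`~peakfit.parameters.ParameterSet`. Fitting minimizes the
unweighted residual sum of squares with the Trust Region Reflective
method by default; bounds come from the parameter registry, constraint
expressions are re-resolved at every residual evaluation so ties hold
exactly along the whole optimization path.

Standard errors derive from the SVD pseudo-inverse of J^T J at the
optimum scaled by the reduced chi-square; profile-likelihood confidence
intervals invert an F-statistic comparison of chi-square ratios
(the conventional F-test construction for nonlinear regression).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import optimize, stats

from . import lineshapes
from .config import ComponentSpec, FitProject, Spectrum
from .exceptions import PeakfitError, UnderdeterminedError
from .parameters import (ParameterSet, build_names, free_parameters,
                         resolve_expressions)
from .statistics import GoodnessOfFit, goodness_of_fit

__all__ = ["FitResult", "ConfidenceReport", "evaluate_model", "fit",
           "confidence_intervals", "component_label"]

#: method aliases that map onto scipy.optimize.least_squares
_LSQ_METHODS = {"least_squares": "trf", "trf": "trf", "dogbox": "dogbox",
                "least": "lm", "leastsq": "lm", "lm": "lm",
                "levenberg-marquardt": "lm"}

#: default solver tolerances (tight: parameter recovery to ~1e-8 relative)
_LSQ_DEFAULTS = {"ftol": 1e-12, "xtol": 1e-12, "gtol": 1e-12, "max_nfev": 20000}


def component_label(comp: ComponentSpec) -> str:
    return f"{comp.kind}_{comp.index}"


def _component_attrs(ps: ParameterSet, comp: ComponentSpec,
                     suffix: Optional[str] = None) -> dict[str, float]:
    attrs = {}
    for attr in comp.attributes:
        name = f"{comp.kind}_{attr}_{comp.index}"
        if suffix is not None:
            name = f"{name}_{suffix}"
        attrs[attr] = ps[name].value
    return attrs


def evaluate_model(ps: ParameterSet, components: Sequence[ComponentSpec],
                   grid, suffix: Optional[str] = None
                   ) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Evaluate the composite model and its per-component curves.

    ``ps`` must already be expression-resolved. Returns
    ``(model_curve, {component_label: curve})`` with
    ``model_curve == sum(curves)`` elementwise.
    """
    grid = np.asarray(grid, dtype=float)
    curves: dict[str, np.ndarray] = {}
    total = np.zeros_like(grid)
    for comp in components:
        attrs = _component_attrs(ps, comp, suffix)
        if comp.kind in lineshapes.PEAK_KINDS:
            curve = lineshapes.eval_peak(comp.kind, grid, attrs)
        elif comp.kind in lineshapes.STEP_KINDS:
            curve = lineshapes.eval_step(comp.kind, grid, attrs)
        else:
            curve = lineshapes.eval_background(comp.kind, grid, attrs)
        curves[component_label(comp)] = curve
        total = total + curve
    return total, curves


@dataclass
class FitResult:
    """Everything a completed fit produced."""

    params: ParameterSet
    model_curve: np.ndarray
    components: dict[str, np.ndarray]
    residual: np.ndarray  # y - model
    gof: GoodnessOfFit
    success: bool
    n_eval: int
    message: str = ""
    covariance: Optional[np.ndarray] = None
    free_names: list[str] = field(default_factory=list)
    spectrum: Optional[Spectrum] = None

    @property
    def best_values(self) -> dict[str, float]:
        return self.params.values()


@dataclass
class ConfidenceInterval:
    """Profile interval for one parameter at one probability level."""

    sigma: float
    probability: float
    lower: Optional[float]  # None = profiling failed to bracket that side
    upper: Optional[float]


@dataclass
class ConfidenceReport:
    """Per-parameter profile confidence intervals at 1/2/3 sigma levels."""

    intervals: dict[str, list[ConfidenceInterval]]

    def table(self):
        import pandas as pd
        rows = []
        for name, cis in self.intervals.items():
            row: dict = {"parameter": name}
            for ci in cis:
                lo = np.nan if ci.lower is None else ci.lower
                hi = np.nan if ci.upper is None else ci.upper
                row[f"-{ci.sigma:g}sigma"] = lo
                row[f"+{ci.sigma:g}sigma"] = hi
            rows.append(row)
        return pd.DataFrame(rows).set_index("parameter")


class _Objective:
    """Residual closure over the parameter registry and the data."""

    def __init__(self, ps: ParameterSet, components: Sequence[ComponentSpec],
                 spectra: Sequence[Spectrum], suffixes: Sequence[Optional[str]]):
        self.ps = ps
        self.components = components
        self.spectra = spectra
        self.suffixes = suffixes
        self.free = free_parameters(ps)

    def set_free(self, values: np.ndarray) -> None:
        for name, v in zip(self.free, values):
            self.ps[name].value = float(v)
        resolve_expressions(self.ps)

    def residual(self, values: np.ndarray) -> np.ndarray:
        self.set_free(values)
        parts = []
        for s, suf in zip(self.spectra, self.suffixes):
            model, _ = evaluate_model(self.ps, self.components, s.x, suf)
            parts.append(model - s.y)
        return np.concatenate(parts)

    def chi2(self, values: np.ndarray) -> float:
        r = self.residual(values)
        return float(r @ r)

    def x0_bounds(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        x0 = np.array([self.ps[n].value for n in self.free])
        lo = np.array([self.ps[n].min for n in self.free])
        hi = np.array([self.ps[n].max for n in self.free])
        return np.clip(x0, lo, hi), lo, hi


def _covariance(jac: np.ndarray, red_chi2: float) -> Optional[np.ndarray]:
    try:
        _, s, vt = np.linalg.svd(jac, full_matrices=False)
    except np.linalg.LinAlgError:  # pragma: no cover
        return None
    threshold = np.finfo(float).eps * max(jac.shape) * (s[0] if s.size else 0.0)
    keep = s > threshold
    if not keep.any():
        return None
    s, vt = s[keep], vt[keep]
    cov = (vt.T / s**2) @ vt * red_chi2
    return 0.5 * (cov + cov.T)  # enforce exact symmetry


def _minimize_core(obj: _Objective, method: str, method_kwargs: dict
                   ) -> tuple[np.ndarray, bool, int, str, Optional[np.ndarray]]:
    """Run the optimizer; returns (x, success, nfev, message, jac-or-None)."""
    x0, lo, hi = obj.x0_bounds()
    n_points = sum(len(s) for s in obj.spectra)
    if n_points <= x0.size:
        raise UnderdeterminedError(
            f"{n_points} data point(s) cannot determine {x0.size} free parameter(s)")
    lsq_method = _LSQ_METHODS.get(method.lower())
    if lsq_method is not None:
        kwargs = dict(_LSQ_DEFAULTS)
        kwargs.update(method_kwargs)
        bounded = np.isfinite(lo).any() or np.isfinite(hi).any()
        if lsq_method == "lm" and bounded:
            lsq_method = "trf"  # LM cannot honor bounds; TRF can
        if lsq_method != "lm":
            kwargs["bounds"] = (lo, hi)
        res = optimize.least_squares(obj.residual, x0, method=lsq_method, **kwargs)
        return res.x, bool(res.success), int(res.nfev), res.message, res.jac
    # any other name: scalar minimization of chi2; no covariance reported
    bounds = None
    if np.isfinite(lo).any() or np.isfinite(hi).any():
        bounds = list(zip(np.where(np.isfinite(lo), lo, None),
                          np.where(np.isfinite(hi), hi, None)))
    res = optimize.minimize(obj.chi2, x0, method=method, bounds=bounds,
                            **method_kwargs)
    return res.x, bool(res.success), int(getattr(res, "nfev", -1)), \
        str(res.message), None


def fit(project: FitProject, spectrum: Spectrum,
        params: Optional[ParameterSet] = None,
        method: Optional[str] = None,
        method_kwargs: Optional[dict] = None) -> FitResult:
    """Fit the project's composite model to one spectrum.

    The optimizer defaults to the project's settings (Trust Region
    Reflective bounded least squares unless configured otherwise);
    ``method``/``method_kwargs`` override them. Non-convergence is
    reported via ``success=False``, never as an exception, so statistics
    can still be inspected.
    """
    ps = params if params is not None else build_names(project.components)
    method = method or project.settings.method
    mk = dict(project.settings.method_kwargs)
    if method_kwargs:
        mk.update(method_kwargs)
    obj = _Objective(ps, project.components, [spectrum], [None])
    if not obj.free:
        raise PeakfitError("model has no free parameters to fit")
    x, success, nfev, message, jac = _minimize_core(obj, method, mk)
    obj.set_free(x)
    model, curves = evaluate_model(ps, project.components, spectrum.x)
    residual = spectrum.y - model
    gof = goodness_of_fit(residual, k=len(obj.free))
    cov = None
    if jac is not None:
        cov = _covariance(jac, gof.red_chi2)
        if cov is not None:
            stderr = np.sqrt(np.clip(np.diag(cov), 0.0, None))
            for name, se in zip(obj.free, stderr):
                ps[name].stderr = float(se)
    return FitResult(params=ps, model_curve=model, components=curves,
                     residual=residual, gof=gof, success=success, n_eval=nfev,
                     message=message, covariance=cov, free_names=list(obj.free),
                     spectrum=spectrum)


_SIGMA_PROB = {1: 0.6827, 2: 0.9545, 3: 0.9973}


def _f_probability(chi2_fixed: float, chi2_best: float, n: int, k: int) -> float:
    """Probability level at which a 1-parameter freeze is rejected (F-test)."""
    if chi2_fixed <= chi2_best:
        return 0.0
    f_stat = (chi2_fixed / chi2_best - 1.0) * (n - k)
    return float(stats.f.cdf(f_stat, 1, n - k))


def confidence_intervals(project: FitProject, result: FitResult,
                         sigmas: Sequence[float] = (1, 2, 3),
                         max_steps: int = 50) -> ConfidenceReport:
    """Profile-likelihood confidence intervals for every free parameter.

    Each parameter is stepped away from its best value with all other
    free parameters refit; the boundary is where the F-statistic
    comparing the constrained to the unconstrained chi-square crosses
    the requested probability (0.6827/0.9545/0.9973 for 1/2/3 sigma).
    A side that cannot be bracketed (typically a parameter pinned at a
    bound) is reported as ``None``.
    """
    if not result.success:
        raise PeakfitError("confidence intervals require a converged fit")
    spectrum = result.spectrum
    if spectrum is None:
        raise PeakfitError("fit result carries no spectrum")
    n = len(spectrum)
    k = len(result.free_names)
    chi2_best = result.gof.chi2
    if chi2_best <= 0:
        raise PeakfitError("zero residual: confidence profiling is degenerate")
    best = {name: result.params[name].value for name in result.free_names}
    report: dict[str, list[ConfidenceInterval]] = {}

    def prob_at(ps_work: ParameterSet, target: str, value: float) -> float:
        for nm, v in best.items():
            ps_work[nm].value = v
        p = ps_work[target]
        p.value = value
        p.vary = False
        try:
            if any(q.is_free for q in ps_work):
                sub = fit(project, spectrum, params=ps_work)
                chi2_fixed = sub.gof.chi2
            else:  # single-parameter model: nothing left to refit
                resolve_expressions(ps_work)
                model, _ = evaluate_model(ps_work, project.components, spectrum.x)
                r = spectrum.y - model
                chi2_fixed = float(r @ r)
        finally:
            p.vary = True
        return _f_probability(chi2_fixed, chi2_best, n, k)

    for name in result.free_names:
        p = result.params[name]
        se = p.stderr if p.stderr else abs(p.value) * 0.01 + 1e-8
        cis = []
        for sig in sigmas:
            target_prob = _SIGMA_PROB.get(int(sig), float(
                2 * stats.norm.cdf(sig) - 1))
            sides: dict[int, Optional[float]] = {}
            for direction in (-1, 1):
                ps_work = result.params.copy()
                lo_b, hi_b = p.min, p.max
                val, prob, prev = best[name], 0.0, best[name]
                found = None
                for step in range(1, max_steps + 1):
                    val = best[name] + direction * se * (sig * step / 4.0) ** 1.5
                    if val <= lo_b or val >= hi_b:
                        break
                    prob = prob_at(ps_work, name, val)
                    if prob >= target_prob:
                        try:
                            found = optimize.brentq(
                                lambda v: prob_at(ps_work, name, v) - target_prob,
                                prev, val, xtol=abs(se) * 1e-3 + 1e-12)
                        except ValueError:  # pragma: no cover
                            found = val
                        break
                    prev = val
                sides[direction] = found
            cis.append(ConfidenceInterval(sigma=float(sig),
                                          probability=target_prob,
                                          lower=sides[-1], upper=sides[1]))
        report[name] = cis
    # restore the best-fit values the profiling perturbed
    for nm, v in best.items():
        result.params[nm].value = v
    resolve_expressions(result.params)
    return ConfidenceReport(intervals=report)
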