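"""Simultaneous (global) fitting of several spectra with shared centers.

One declarative component list is expanded into per-spectrum parameter
copies (``gaussian_center_1`` becomes ``gaussian_center_1_1``,
``gaussian_center_1_2``, ...). Every center parameter of spectra beyond
the first is bound by an autogenerated constraint expression to the
first spectrum's center, so peak energies stay identical across spectra
at machine precision while amplitudes and widths remain free per
spectrum (optionally widths can be tied too). The spectra are stacked
into one residual vector for the optimizer and unstacked afterwards.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .config import ComponentSpec, FitProject, Spectrum
from .exceptions import InputValidationError, PeakfitError
from .parameters import Parameter, ParameterSet, build_names
from .solver import FitResult, _Objective, _covariance, _minimize_core, \
    evaluate_model, fit
from .statistics import GoodnessOfFit, goodness_of_fit

__all__ = ["StackedData", "stack", "unstack", "expand_model",
           "fit_simultaneous", "TIED_WIDTH_ATTRS"]

#: attributes treated as peak positions (always tied across spectra)
TIED_CENTER_ATTRS = ("center",)
#: attributes additionally tied when ``tie_widths`` is enabled
TIED_WIDTH_ATTRS = ("fwhmg", "fwhml", "fwhmv", "sigma")


@dataclass
class StackedData:
    """Spectra concatenated row-wise, with provenance to unstack exactly."""

    x: np.ndarray
    y: np.ndarray
    spectrum_id: np.ndarray  # 0-based spectrum index per row
    slices: list[tuple[int, int]]
    labels: list[tuple[str, str]]

    @property
    def n_rows(self) -> int:
        return self.x.size


def stack(spectra: Sequence[Spectrum]) -> StackedData:
    """Concatenate spectra in input order into one combined structure."""
    if not spectra:
        raise InputValidationError("cannot stack an empty spectrum list")
    slices, start = [], 0
    for s in spectra:
        slices.append((start, start + len(s)))
        start += len(s)
    return StackedData(
        x=np.concatenate([s.x for s in spectra]),
        y=np.concatenate([s.y for s in spectra]),
        spectrum_id=np.concatenate(
            [np.full(len(s), i) for i, s in enumerate(spectra)]),
        slices=slices,
        labels=[(s.x_label, s.y_label) for s in spectra])


def unstack(data: StackedData) -> list[Spectrum]:
    """Exact inverse of :func:`stack`."""
    out = []
    for (lo, hi), (xl, yl) in zip(data.slices, data.labels):
        out.append(Spectrum(x=data.x[lo:hi].copy(), y=data.y[lo:hi].copy(),
                            x_label=xl, y_label=yl))
    return out


def _suffixed_expr(expr: str, base_names: set[str], suffix: str) -> str:
    """Rewrite user expressions so base parameter names refer to the same
    spectrum's copy."""
    def repl(match: re.Match) -> str:
        word = match.group(0)
        return f"{word}_{suffix}" if word in base_names else word
    return re.sub(r"[A-Za-z_][A-Za-z0-9_]*", repl, expr)


def expand_model(components: Sequence[ComponentSpec], n_spectra: int,
                 tie_widths: bool = False) -> ParameterSet:
    """Per-spectrum parameter copies with autogenerated center ties.

    For ``n_spectra == 1`` this is identical to the single-spectrum
    registry. Otherwise each base parameter is duplicated with suffixes
    ``_1 .. _n``; centers (and widths, if ``tie_widths``) of every
    spectrum beyond the first receive an expression pointing at the
    first spectrum's copy, freezing those values across spectra.
    """
    if n_spectra < 1:
        raise InputValidationError(f"n_spectra must be >= 1, got {n_spectra}")
    if n_spectra == 1:
        return build_names(list(components))
    base = build_names(list(components))
    base_names = set(base.names())
    tied = TIED_CENTER_ATTRS + (TIED_WIDTH_ATTRS if tie_widths else ())
    ps = ParameterSet()
    for j in range(1, n_spectra + 1):
        suffix = str(j)
        for comp in components:
            for attr, spec in comp.attributes.items():
                name = f"{comp.kind}_{attr}_{comp.index}_{suffix}"
                expr = spec.expr
                if expr is not None:
                    expr = _suffixed_expr(expr, base_names, suffix)
                if j > 1 and attr in tied and expr is None:
                    expr = f"{comp.kind}_{attr}_{comp.index}_1"
                ps.add(Parameter(name=name, value=spec.value, min=spec.min,
                                 max=spec.max, vary=spec.vary, expr=expr))
    return ps


def fit_simultaneous(project: FitProject, spectra: Sequence[Spectrum],
                     params: Optional[ParameterSet] = None,
                     method: Optional[str] = None,
                     method_kwargs: Optional[dict] = None,
                     tie_widths: Optional[bool] = None,
                     ) -> tuple[list[FitResult], GoodnessOfFit]:
    """Fit one component model to all spectra at once.

    Returns one :class:`FitResult` per spectrum (sharing the expanded
    parameter registry; each carries its own curves, residual slice and
    the *joint* goodness of fit — AIC/BIC/chi-square are global
    quantities of the stacked residual, while regression metrics are
    per spectrum) plus the joint :class:`GoodnessOfFit`.
    """
    spectra = list(spectra)
    if not spectra:
        raise InputValidationError("no spectra to fit")
    if len(spectra) == 1:
        res = fit(project, spectra[0], params=params, method=method,
                  method_kwargs=method_kwargs)
        return [res], res.gof
    if tie_widths is None:
        tie_widths = bool(project.settings.tie_widths)
    ps = params if params is not None else expand_model(
        project.components, len(spectra), tie_widths=tie_widths)
    method = method or project.settings.method
    mk = dict(project.settings.method_kwargs)
    if method_kwargs:
        mk.update(method_kwargs)
    suffixes = [str(j) for j in range(1, len(spectra) + 1)]
    obj = _Objective(ps, project.components, spectra, suffixes)
    if not obj.free:
        raise PeakfitError("expanded model has no free parameters")
    x, success, nfev, message, jac = _minimize_core(obj, method, mk)
    obj.set_free(x)
    joint_residual = -obj.residual(x)  # y - model per stacked row
    joint_gof = goodness_of_fit(joint_residual, k=len(obj.free))
    if jac is not None:
        cov = _covariance(jac, joint_gof.red_chi2)
        if cov is not None:
            for name, se in zip(obj.free,
                                np.sqrt(np.clip(np.diag(cov), 0.0, None))):
                ps[name].stderr = float(se)
    else:
        cov = None
    results = []
    offset = 0
    for s, suf in zip(spectra, suffixes):
        model, curves = evaluate_model(ps, project.components, s.x, suf)
        residual = s.y - model
        results.append(FitResult(
            params=ps, model_curve=model, components=curves,
            residual=residual, gof=joint_gof, success=success, n_eval=nfev,
            message=message, covariance=cov, free_names=list(obj.free),
            spectrum=s))
        offset += len(s)
    return results, joint_gof
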