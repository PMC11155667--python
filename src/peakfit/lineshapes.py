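"""FWHM-parameterized lineshape, step, and background kernels.

All peak profiles follow the *area* convention: ``amplitude`` is the
integrated area of the peak, not its height, so intensities are directly
comparable across Gaussian, Lorentzian, pseudo-Voigt and Voigt components.
Widths are always full widths at half maximum (FWHM) in abscissa units
(typically eV), the parameterization spectroscopists quote.

Conversions used throughout:

* Gaussian standard deviation   ``sigma = fwhm / (2*sqrt(2*ln 2))``
* Lorentzian half-width         ``gamma_L = fwhm / 2``
* Voigt profile: real part of the Faddeeva function ``w(z)`` with
  ``z = (x - center + i*gamma) / (sigma*sqrt(2))`` where ``sigma`` comes
  from ``fwhmv`` and ``gamma`` defaults to ``fwhmv / 2`` when absent.
* pseudo-Voigt: ``amplitude * [fraction * L + (1 - fraction) * G]`` with a
  single shared FWHM (``fwhmv``) and mixing fraction (default 0.5).
"""

from __future__ import annotations

import numpy as np
from scipy.special import erf, expit, wofz

from .exceptions import InputValidationError, ModelDefinitionError

__all__ = [
    "PEAK_KINDS",
    "STEP_KINDS",
    "BACKGROUND_KINDS",
    "eval_peak",
    "eval_step",
    "eval_background",
]

#: sqrt(2 ln 2): FWHM of a unit-sigma Gaussian is 2*_S2LN2.
_S2LN2 = np.sqrt(2.0 * np.log(2.0))

PEAK_KINDS = ("gaussian", "lorentzian", "pseudovoigt", "voigt")
STEP_KINDS = ("heaviside", "arctan", "erf", "logistic", "cumulative_gaussian")
BACKGROUND_KINDS = ("constant", "linear", "polynomial", "exponential")

#: Fig-4 style defaults applied when an attribute dict omits entries.
PEAK_DEFAULTS = {"amplitude": 1.0, "center": 0.0, "fwhmg": 1.0, "fwhml": 1.0,
                 "fwhmv": 1.0, "fraction": 0.5}


def _width(attrs: dict, key: str) -> float:
    w = float(attrs.get(key, PEAK_DEFAULTS[key]))
    if not w > 0.0:
        raise InputValidationError(f"{key} must be > 0, got {w}")
    return w


def _gaussian(x, amplitude, center, fwhm):
    sigma = fwhm / (2.0 * _S2LN2)
    return (amplitude / (sigma * np.sqrt(2.0 * np.pi))
            * np.exp(-((x - center) ** 2) / (2.0 * sigma**2)))


def _lorentzian(x, amplitude, center, fwhm):
    gamma = fwhm / 2.0
    return amplitude * gamma / (np.pi * ((x - center) ** 2 + gamma**2))


def _voigt(x, amplitude, center, fwhm, gamma):
    sigma = fwhm / (2.0 * _S2LN2)
    z = ((x - center) + 1j * gamma) / (sigma * np.sqrt(2.0))
    return amplitude * np.real(wofz(z)) / (sigma * np.sqrt(2.0 * np.pi))


def eval_peak(kind: str, grid, attrs: dict) -> np.ndarray:
    """Evaluate a peak profile on ``grid``.

    Parameters
    ----------
    kind
        One of :data:`PEAK_KINDS`.
    grid
        Abscissa values (finite).
    attrs
        Attribute mapping; missing entries fall back to the package
        defaults (amplitude 1, center 0, width 1, fraction 0.5,
        gamma = fwhmv/2).

    Returns
    -------
    numpy.ndarray
        Intensity with the same shape as ``grid``; integrates to
        ``amplitude`` over an unbounded grid.
    """
    x = np.asarray(grid, dtype=float)
    amplitude = float(attrs.get("amplitude", PEAK_DEFAULTS["amplitude"]))
    center = float(attrs.get("center", PEAK_DEFAULTS["center"]))
    if kind == "gaussian":
        return _gaussian(x, amplitude, center, _width(attrs, "fwhmg"))
    if kind == "lorentzian":
        return _lorentzian(x, amplitude, center, _width(attrs, "fwhml"))
    if kind == "pseudovoigt":
        fwhm = _width(attrs, "fwhmv")
        fraction = float(attrs.get("fraction", PEAK_DEFAULTS["fraction"]))
        if not 0.0 <= fraction <= 1.0:
            raise InputValidationError(f"fraction must be in [0, 1], got {fraction}")
        return amplitude * (fraction * _lorentzian(x, 1.0, center, fwhm)
                            + (1.0 - fraction) * _gaussian(x, 1.0, center, fwhm))
    if kind == "voigt":
        fwhm = _width(attrs, "fwhmv")
        gamma = float(attrs.get("gamma", fwhm / 2.0))
        if gamma < 0.0:
            raise InputValidationError(f"gamma must be >= 0, got {gamma}")
        return _voigt(x, amplitude, center, fwhm, gamma)
    raise ModelDefinitionError(
        f"unknown peak kind {kind!r}; supported: {', '.join(PEAK_KINDS)}")


def eval_step(kind_tag: str, grid, attrs: dict) -> np.ndarray:
    """Evaluate a monotone step/edge profile.

    All steps rise from 0 to ``amplitude`` with inflection at ``center``
    and width scale ``sigma``; ``cumulative_gaussian`` is the integral of
    a Gaussian and is the conventional model for an absorption edge jump.
    """
    x = np.asarray(grid, dtype=float)
    amplitude = float(attrs.get("amplitude", 1.0))
    center = float(attrs.get("center", 0.0))
    sigma = float(attrs.get("sigma", 1.0))
    if not sigma > 0.0:
        raise InputValidationError(f"sigma must be > 0, got {sigma}")
    t = (x - center) / sigma
    if kind_tag == "heaviside":
        return amplitude * np.heaviside(t, 0.5)
    if kind_tag == "arctan":
        return amplitude * (0.5 + np.arctan(t) / np.pi)
    if kind_tag == "erf":
        return amplitude * 0.5 * (1.0 + erf(t))
    if kind_tag == "logistic":
        return amplitude * expit(t)
    if kind_tag == "cumulative_gaussian":
        return amplitude * 0.5 * (1.0 + erf(t / np.sqrt(2.0)))
    raise ModelDefinitionError(
        f"unknown step kind {kind_tag!r}; supported: {', '.join(STEP_KINDS)}")


#: coefficient names, in order, expected by each background kind
BACKGROUND_COEFFS = {
    "constant": ("amplitude",),
    "linear": ("slope", "intercept"),
    "polynomial": ("c0", "c1", "c2", "c3"),
    "exponential": ("amplitude", "decay"),
}


def eval_background(kind: str, grid, coeffs) -> np.ndarray:
    """Evaluate a slowly varying background.

    ``coeffs`` may be a mapping (named coefficients) or a sequence in the
    order given by :data:`BACKGROUND_COEFFS`. ``polynomial`` accepts one
    to four ascending coefficients c0 + c1*x + c2*x^2 + c3*x^3.
    """
    x = np.asarray(grid, dtype=float)
    if kind not in BACKGROUND_KINDS:
        raise ModelDefinitionError(
            f"unknown background kind {kind!r}; supported: {', '.join(BACKGROUND_KINDS)}")
    names = BACKGROUND_COEFFS[kind]
    if isinstance(coeffs, dict):
        unknown = set(coeffs) - set(names)
        if unknown:
            raise InputValidationError(
                f"{kind} background takes {names}, got unexpected {sorted(unknown)}")
        if kind == "polynomial":
            vals = [float(coeffs.get(n, 0.0)) for n in names]
            if not coeffs:
                raise InputValidationError("polynomial background needs >= 1 coefficient")
        else:
            missing = set(names) - set(coeffs)
            if missing:
                raise InputValidationError(
                    f"{kind} background missing coefficients {sorted(missing)}")
            vals = [float(coeffs[n]) for n in names]
    else:
        vals = [float(v) for v in coeffs]
        if kind == "polynomial":
            if not 1 <= len(vals) <= len(names):
                raise InputValidationError(
                    f"polynomial background takes 1..{len(names)} coefficients, got {len(vals)}")
        elif len(vals) != len(names):
            raise InputValidationError(
                f"{kind} background takes {len(names)} coefficients {names}, got {len(vals)}")
    if kind == "constant":
        return np.full_like(x, vals[0])
    if kind == "linear":
        slope, intercept = vals
        return slope * x + intercept
    if kind == "polynomial":
        return np.polynomial.polynomial.polyval(x, np.asarray(vals))
    # exponential: amplitude * exp(-x / decay)
    amplitude, decay = vals
    if decay == 0.0:
        raise InputValidationError("exponential decay must be nonzero")
    return amplitude * np.exp(-x / decay)
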