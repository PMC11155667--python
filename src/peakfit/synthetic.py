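"""Seeded synthetic spectra with known ground truth.

Every generated spectrum is the exact composite of its declared
components plus homoscedastic Gaussian noise from a stated seed, so the
generator is its own oracle: fits can be judged against the truth table
that produced the data. ``make_xas_pair`` emulates a normalized
transition-metal K-edge absorption spectrum — two weak pre-edge peaks,
three rising-edge peaks, and a cumulative-Gaussian edge jump — on the
146-point 7105–7130 eV grid typical of such measurements. All truth
values here are synthetic package constants, not fitted values from any
experiment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from .config import ComponentSpec, FitProject, ParameterSpec, Settings, Spectrum
from .solver import evaluate_model
from .parameters import build_names

__all__ = ["TruthTable", "make_spectrum", "make_xas_pair",
           "truth_project", "write_csv", "XAS_GRID"]

#: abscissa used by the XAS-like generator: 146 points over 7105-7130 eV
XAS_GRID = (7105.0, 7130.0, 146)


@dataclass(frozen=True)
class TruthTable:
    """Complete recipe for one synthetic spectrum (bitwise reproducible)."""

    components: tuple[tuple[str, tuple[tuple[str, float], ...]], ...]
    noise_sd: float = 0.0
    seed: int = 0
    grid: tuple[float, float, int] = (0.0, 10.0, 101)

    @staticmethod
    def build(components: Sequence[tuple[str, dict]], noise_sd: float = 0.0,
              seed: int = 0, grid: tuple[float, float, int] = (0.0, 10.0, 101)
              ) -> "TruthTable":
        frozen = tuple((kind, tuple(sorted(attrs.items())))
                       for kind, attrs in components)
        return TruthTable(components=frozen, noise_sd=noise_sd, seed=seed,
                          grid=grid)

    def component_dicts(self) -> list[tuple[str, dict]]:
        return [(kind, dict(attrs)) for kind, attrs in self.components]

    def abscissa(self) -> np.ndarray:
        lo, hi, n = self.grid
        return np.linspace(lo, hi, n)


def _component_specs(truth: TruthTable, vary_all: bool = True,
                     perturb: Optional[np.random.Generator] = None,
                     rel: float = 0.0) -> list[ComponentSpec]:
    specs = []
    for i, (kind, attrs) in enumerate(truth.component_dicts(), start=1):
        pspecs = {}
        width = next((attrs[w] for w in ("fwhmg", "fwhml", "fwhmv", "sigma")
                      if w in attrs), 1.0)
        for name, value in attrs.items():
            v = value
            if perturb is not None and rel > 0.0:
                if name == "center":
                    # centers live on an absolute axis: offset by a fraction
                    # of the peak width, not of the energy value
                    v = value + rel * width * perturb.uniform(-1.0, 1.0)
                elif value == 0.0:
                    v = rel * perturb.uniform(-1.0, 1.0)
                else:
                    v = value * (1.0 + rel * perturb.uniform(-1.0, 1.0))
            positive = name in {"fwhmg", "fwhml", "fwhmv", "sigma"}
            lo = 1e-6 if positive else -np.inf
            pspecs[name] = ParameterSpec(value=float(v), vary=vary_all,
                                         min=lo, max=np.inf)
        specs.append(ComponentSpec(index=str(i), kind=kind, attributes=pspecs))
    return specs


def truth_project(truth: TruthTable, init_rel_error: float = 0.0,
                  init_seed: Optional[int] = None, **settings) -> FitProject:
    """A :class:`FitProject` whose initial values are the truth, optionally
    perturbed by a uniform relative error (for recovery studies)."""
    rng = np.random.default_rng(init_seed) if init_seed is not None else None
    specs = _component_specs(truth, perturb=rng, rel=init_rel_error)
    return FitProject(settings=Settings(**settings),
                      description={"source": "synthetic truth"},
                      components=specs)


def make_spectrum(truth: TruthTable, x_label: str = "energy",
                  y_label: str = "intensity") -> tuple[Spectrum, np.ndarray]:
    """Generate one spectrum: exact composite curve + seeded Gaussian noise.

    Returns ``(spectrum, clean_curve)`` so tests can separate noise from
    signal.
    """
    x = truth.abscissa()
    specs = _component_specs(truth)
    ps = build_names(specs)
    clean, _ = evaluate_model(ps, specs, x)
    y = clean
    if truth.noise_sd > 0.0:
        rng = np.random.default_rng(truth.seed)
        y = clean + rng.normal(0.0, truth.noise_sd, size=x.size)
    return Spectrum(x=x, y=y.copy(), x_label=x_label, y_label=y_label), clean


#: synthetic XAS-like truth (energies in eV, areas in intensity*eV):
#: 2 pre-edge Gaussians, 3 rising-edge Gaussians, cumulative-Gaussian edge
_XAS_CENTERS = (7112.3, 7114.0, 7116.5, 7119.5, 7122.5, 7124.0)
_XAS_BASE = (
    ("gaussian", {"amplitude": 0.055, "center": _XAS_CENTERS[0], "fwhmg": 1.2}),
    ("gaussian", {"amplitude": 0.069, "center": _XAS_CENTERS[1], "fwhmg": 1.3}),
    ("gaussian", {"amplitude": 0.30, "center": _XAS_CENTERS[2], "fwhmg": 1.6}),
    ("gaussian", {"amplitude": 0.45, "center": _XAS_CENTERS[3], "fwhmg": 1.8}),
    ("gaussian", {"amplitude": 0.35, "center": _XAS_CENTERS[4], "fwhmg": 2.0}),
    ("cumulative_gaussian", {"amplitude": 1.0, "center": _XAS_CENTERS[5],
                             "sigma": 1.2}),
)
#: per-spectrum amplitude scale factors (shared centers, differing weights)
_XAS_AMP_SCALE = (1.0, 1.2)


def make_xas_pair(seed: int = 0, noise_sd: float = 0.005
                  ) -> tuple[list[Spectrum], list[TruthTable]]:
    """Two XAS-like spectra with identical peak energies but different
    amplitudes, each 146 points on 7105-7130 eV.

    The pair is the canonical input for simultaneous-fitting tests:
    centers agree across the two spectra by construction, and the two
    pre-edge peaks sit below the edge-jump center.
    """
    spectra, truths = [], []
    for j, scale in enumerate(_XAS_AMP_SCALE):
        comps = []
        for kind, attrs in _XAS_BASE:
            a = dict(attrs)
            a["amplitude"] = round(a["amplitude"] * scale, 6)
            comps.append((kind, a))
        truth = TruthTable.build(comps, noise_sd=noise_sd,
                                 seed=seed * 2 + j, grid=XAS_GRID)
        s, _ = make_spectrum(truth, y_label=f"norm_{j + 1}")
        spectra.append(s)
        truths.append(truth)
    return spectra, truths


#: generic 6-peak truth for model-selection studies: evenly spaced
#: Gaussians, widths well below the spacing, amplitudes O(1)
SIX_PEAK_TRUTH = tuple(
    ("gaussian", {"amplitude": a, "center": c, "fwhmg": 1.5})
    for a, c in zip((1.0, 0.8, 1.2, 0.9, 1.1, 0.7),
                    (3.0, 6.0, 9.0, 12.0, 15.0, 18.0)))
SIX_PEAK_GRID = (0.0, 21.0, 400)
SIX_PEAK_NOISE_SD = 0.02


def make_six_peak_spectrum(seed: int = 0) -> tuple[Spectrum, TruthTable]:
    """One noisy realization of the 6-peak model-selection truth."""
    truth = TruthTable.build(list(SIX_PEAK_TRUTH), noise_sd=SIX_PEAK_NOISE_SD,
                             seed=seed, grid=SIX_PEAK_GRID)
    s, _ = make_spectrum(truth)
    return s, truth


def candidate_peaks_project(n_peaks: int, x: np.ndarray) -> FitProject:
    """Generic k-Gaussian candidate model for a spectrum on grid ``x``:
    centers initialized evenly spaced across the interior, bounded to the
    grid; amplitudes nonnegative; widths in a broad positive band."""
    lo, hi = float(x.min()), float(x.max())
    centers = np.linspace(lo + 1.5, hi - 1.5, n_peaks)
    comps = []
    for i, c in enumerate(centers, start=1):
        comps.append(ComponentSpec(index=str(i), kind="gaussian", attributes={
            "amplitude": ParameterSpec(value=1.0, min=0.0, max=50.0),
            "center": ParameterSpec(value=float(c), min=lo, max=hi),
            "fwhmg": ParameterSpec(value=1.5, min=0.3, max=8.0)}))
    return FitProject(settings=Settings(),
                      description={"source": "nested candidate model"},
                      components=comps)


def write_csv(path: Union[str, Path], spectra: Sequence[Spectrum],
              x_label: str = "energy") -> Path:
    """Emit spectra as one CSV in the package's input dialect
    (one abscissa column + one intensity column per spectrum)."""
    import pandas as pd
    path = Path(path)
    data = {x_label: spectra[0].x}
    for s in spectra:
        if not np.array_equal(s.x, spectra[0].x):
            raise ValueError("write_csv requires a shared abscissa")
        data[s.y_label] = s.y
    pd.DataFrame(data).to_csv(path, index=False)
    return path
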