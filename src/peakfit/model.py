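"""High-level Model/Results interface.

:class:`SpectralModel` binds a declarative :class:`~peakfit.config.FitProject`
to one or more spectra (a list engages simultaneous fitting with shared
peak energies); ``fit()`` returns :class:`SpectralFitResults` carrying
best-fit parameters, standard errors, per-component curves, the full
statistics suite, and exporters for CSV/JSON outputs and the lock
report.

    >>> from peakfit import SpectralModel, synthetic
    >>> spectra, truths = synthetic.make_xas_pair(seed=7)
    >>> project = synthetic.truth_project(truths[0], init_rel_error=0.1,
    ...                                   init_seed=7)
    >>> res = SpectralModel(project, spectra).fit()
    >>> print(res.summary())            # doctest: +SKIP
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from . import report as _report
from .config import (FitProject, Spectrum, parse_input, preprocess,
                     read_spectrum)
from .exceptions import PeakfitError
from .simultaneous import fit_simultaneous
from .solver import FitResult, confidence_intervals
from .statistics import MetricLedger, six_tables

__all__ = ["SpectralModel", "SpectralFitResults"]


class SpectralModel:
    """A composite lineshape model bound to data, ready to fit.

    Parameters
    ----------
    project
        Parsed declarative model (settings, description, components).
    spectra
        One :class:`Spectrum` or a sequence; more than one spectrum
        engages simultaneous fitting with centers tied across spectra.
    apply_settings
        Apply the project's ``energy_shift``/``energy_range`` filters to
        the spectra at construction (default True).
    """

    def __init__(self, project: FitProject,
                 spectra: Union[Spectrum, Sequence[Spectrum]],
                 apply_settings: bool = True):
        self.project = project
        if isinstance(spectra, Spectrum):
            spectra = [spectra]
        spectra = list(spectra)
        if not spectra:
            raise PeakfitError("no spectra given")
        if apply_settings:
            s = project.settings
            if s.energy_shift or s.energy_range is not None:
                spectra = [preprocess(sp, shift=s.energy_shift,
                                      range=s.energy_range) for sp in spectra]
        self.spectra = spectra

    @classmethod
    def from_files(cls, data_path: Union[str, Path],
                   input_path: Union[str, Path],
                   x_column: Optional[str] = None,
                   y_column: Optional[Union[str, Sequence[str]]] = None,
                   **setting_overrides) -> "SpectralModel":
        """Build a model from a delimited data file and an input document.

        Precedence for settings is: explicit arguments here > the input
        file's settings block > package defaults. A list-valued
        ``y_column`` selects several intensity columns and triggers
        simultaneous mode.
        """
        project = parse_input(input_path)
        s = project.settings
        merged = {k: v for k, v in setting_overrides.items() if v is not None}
        for key, value in merged.items():
            setattr(s, key, value)
        x_col = x_column or s.x_column
        y_cols = y_column if y_column is not None else s.y_column
        if y_cols is None or isinstance(y_cols, str):
            y_cols = [y_cols]
        spectra = [read_spectrum(data_path, x_column=x_col, y_column=yc)
                   for yc in y_cols]
        return cls(project, spectra)

    @classmethod
    def from_dataframe(cls, frame, project: FitProject,
                       x_column: Optional[str] = None,
                       y_column: Optional[Union[str, Sequence[str]]] = None
                       ) -> "SpectralModel":
        """Build a model from a pandas DataFrame of spectra columns."""
        x_col = x_column or project.settings.x_column or frame.columns[0]
        y_cols = y_column or project.settings.y_column or frame.columns[1]
        if isinstance(y_cols, str):
            y_cols = [y_cols]
        spectra = []
        for yc in y_cols:
            sub = frame[[x_col, yc]].dropna()
            spectra.append(Spectrum(x=sub[x_col].to_numpy(float),
                                    y=sub[yc].to_numpy(float),
                                    x_label=str(x_col), y_label=str(yc)))
        return cls(project, spectra)

    @property
    def simultaneous(self) -> bool:
        return len(self.spectra) > 1

    def fit(self, method: Optional[str] = None,
            method_kwargs: Optional[dict] = None) -> "SpectralFitResults":
        """Run the bounded least-squares fit and collect results."""
        results, joint_gof = fit_simultaneous(
            self.project, self.spectra, method=method,
            method_kwargs=method_kwargs)
        return SpectralFitResults(self, results, joint_gof)


class SpectralFitResults:
    """Estimates, uncertainties, diagnostics and exporters for one fit."""

    def __init__(self, model: SpectralModel, results: list[FitResult],
                 joint_gof):
        self.model = model
        self.results = results
        self.gof = joint_gof
        self.params = results[0].params  # shared registry
        self.success = all(r.success for r in results)

    @property
    def best_values(self) -> dict[str, float]:
        return self.params.values()

    @property
    def stderr(self) -> dict[str, Optional[float]]:
        return {p.name: p.stderr for p in self.params}

    def tables(self, spectrum_index: int = 0):
        """The six statistics tables for one spectrum."""
        r = self.results[spectrum_index]
        return six_tables(r.spectrum, r)

    def summary(self) -> str:
        """Printable report: six statistics tables per spectrum."""
        blocks = []
        for i, r in enumerate(self.results):
            if len(self.results) > 1:
                blocks.append(f"=== Spectrum {i + 1}: {r.spectrum.y_label} ===")
            for title, frame in six_tables(r.spectrum, r).items():
                blocks.append(f"--- {title} ---")
                blocks.append(frame.to_string())
                blocks.append("")
        blocks.append(f"fit success: {self.success}  "
                      f"(function evaluations: {self.results[0].n_eval})")
        return "\n".join(blocks)

    def conf_intervals(self, sigmas: Sequence[float] = (1, 2, 3)):
        """Profile-likelihood confidence intervals (single-spectrum fits)."""
        if self.model.simultaneous:
            raise PeakfitError(
                "confidence profiling is defined for single-spectrum fits")
        return confidence_intervals(self.model.project, self.results[0],
                                    sigmas=sigmas)

    def record_metrics(self, ledger: Optional[MetricLedger] = None,
                       metrics: Optional[Sequence[str]] = None) -> MetricLedger:
        """Append this fit's statistics to a metric ledger."""
        if ledger is None:
            ledger = MetricLedger(metrics=tuple(metrics)
                                  if metrics else ("aic", "bic", "mse"))
        ledger.append(self.results[0])
        return ledger

    def save(self, basename: Union[str, Path]) -> list[Path]:
        """Write CSV/JSON outputs (per spectrum) plus the ``.lock`` report."""
        basename = Path(basename)
        files: list[Path] = []
        if len(self.results) == 1:
            files += _report.write_outputs(self.results[0], basename,
                                           project=self.model.project)
        else:
            for i, r in enumerate(self.results, start=1):
                files += _report.write_outputs(
                    r, basename.with_name(f"{basename.name}_spectrum_{i}"),
                    project=self.model.project)
        lock = _report.write_lock(self.model.project, self.model.spectra,
                                  self.results,
                                  basename.with_name(basename.name + ".lock"))
        files.append(lock.path)
        return files

    def lock(self, path: Union[str, Path]):
        """Write only the tamper-evident lock report."""
        return _report.write_lock(self.model.project, self.model.spectra,
                                  self.results, path)

    def plot(self, path: Optional[Union[str, Path]] = None,
             spectrum_index: int = 0):
        """Static figure: residual with linear trend band on top,
        data / fit / components below."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        from .statistics import residual_trend
        r = self.results[spectrum_index]
        s = r.spectrum
        fig, (ax0, ax1) = plt.subplots(
            2, 1, sharex=True, figsize=(7, 6),
            gridspec_kw={"height_ratios": [1, 3]})
        ax0.plot(s.x, r.residual, ".", color="firebrick", ms=3,
                 label="residual")
        try:
            trend = residual_trend(s.x, r.residual)
            ax0.plot(s.x, trend.line, "-", color="firebrick", lw=1)
            ax0.fill_between(s.x, trend.band_lower, trend.band_upper,
                             color="firebrick", alpha=0.2)
        except PeakfitError:
            pass
        ax0.axhline(0.0, color="0.6", lw=0.8)
        ax0.set_ylabel("residual")
        ax1.plot(s.x, s.y, "-", color="steelblue", label=s.y_label)
        ax1.plot(s.x, r.model_curve, "--", color="navy", label="fit")
        for name, curve in r.components.items():
            ax1.plot(s.x, curve, ":", lw=1, label=name)
        ax1.set_xlabel(s.x_label)
        ax1.set_ylabel(s.y_label)
        ax1.legend(fontsize=7)
        fig.tight_layout()
        if path is not None:
            fig.savefig(path, dpi=120)
            plt.close(fig)
            return Path(path)
        return fig
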