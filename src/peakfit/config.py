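"""Declarative fit-project input and spectrum ingestion.

A fit project is a JSON, YAML, or TOML document with two top-level blocks::

    {
      "settings": { "x_column": ..., "y_column": ...,
                    "energy_shift": ..., "energy_range": [lo, hi],
                    "method": ..., "method_kwargs": {...} },
      "fitting": {
        "description": { ...free metadata... },
        "peaks": {
          "1": { "gaussian": {
                   "amplitude": {"min": 0, "max": 2, "vary": true, "value": 1},
                   "center":    {...}, "fwhmg": {...} } },
          "2": { ... }
        }
      }
    }

Component indices are string integers; each component is one lineshape
kind with per-attribute parameter specs (min/max/vary/value/expr).
Attributes a user omits fall back to amplitude=1, center=0, width=1 with
unbounded vary=true specs. The three serialization formats are fully
equivalent.
"""

from __future__ import annotations

import json
import logging
import math
import tomllib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional, Union

import numpy as np
import pandas as pd
import pydantic
import yaml

from . import lineshapes
from .exceptions import InputValidationError, ModelDefinitionError, SpectrumError

logger = logging.getLogger(__name__)

__all__ = [
    "ParameterSpec", "ComponentSpec", "Settings", "FitProject", "Spectrum",
    "parse_input", "serialize", "read_spectrum", "preprocess",
    "SUPPORTED_KINDS", "canonical_attributes",
]

SUPPORTED_KINDS = (lineshapes.PEAK_KINDS + lineshapes.STEP_KINDS
                   + lineshapes.BACKGROUND_KINDS)

#: width attribute per peak kind (the FWHM the user fits)
_PEAK_WIDTH = {"gaussian": "fwhmg", "lorentzian": "fwhml",
               "pseudovoigt": "fwhmv", "voigt": "fwhmv"}

#: default initial values when a spec omits attributes entirely
_ATTR_DEFAULTS = {
    "amplitude": 1.0, "center": 0.0, "fwhmg": 1.0, "fwhml": 1.0, "fwhmv": 1.0,
    "fraction": 0.5, "gamma": 0.5, "sigma": 1.0,
    "slope": 0.0, "intercept": 0.0, "c0": 0.0, "c1": 0.0, "c2": 0.0, "c3": 0.0,
    "decay": 1.0,
}


def canonical_attributes(kind: str) -> tuple[str, ...]:
    """Attributes auto-created for a component of ``kind`` when omitted."""
    if kind in lineshapes.PEAK_KINDS:
        return ("amplitude", "center", _PEAK_WIDTH[kind])
    if kind in lineshapes.STEP_KINDS:
        return ("amplitude", "center", "sigma")
    if kind == "polynomial":
        return ("c0",)
    return lineshapes.BACKGROUND_COEFFS[kind]


def _allowed_attributes(kind: str) -> tuple[str, ...]:
    extra = {"pseudovoigt": ("fraction",), "voigt": ("gamma",),
             "polynomial": ("c0", "c1", "c2", "c3")}
    return canonical_attributes(kind) + extra.get(kind, ())


class ParameterSpec(pydantic.BaseModel):
    """Bounds, initial value, vary flag and optional constraint expression."""

    model_config = pydantic.ConfigDict(extra="forbid")

    min: float = -math.inf
    max: float = math.inf
    vary: bool = True
    value: float = 0.0
    expr: Optional[str] = None

    @pydantic.model_validator(mode="after")
    def _check(self) -> "ParameterSpec":
        if self.expr is not None:
            if "vary" in self.model_fields_set and self.vary:
                raise ValueError("expr and vary=true are mutually exclusive")
            object.__setattr__(self, "vary", False)
        if self.min > self.max:
            raise ValueError(f"min ({self.min}) > max ({self.max})")
        if "value" in self.model_fields_set and not self.min <= self.value <= self.max:
            raise ValueError(
                f"value {self.value} outside bounds [{self.min}, {self.max}]")
        return self


class ComponentSpec(pydantic.BaseModel):
    """One lineshape component: kind + per-attribute parameter specs."""

    model_config = pydantic.ConfigDict(extra="forbid")

    index: str
    kind: str
    attributes: dict[str, ParameterSpec]

    @pydantic.model_validator(mode="after")
    def _check(self) -> "ComponentSpec":
        if self.kind not in SUPPORTED_KINDS:
            raise ValueError(
                f"unsupported lineshape kind {self.kind!r}; "
                f"supported: {', '.join(SUPPORTED_KINDS)}")
        try:
            int(self.index)
        except ValueError:
            raise ValueError(f"component index must be a string integer, got {self.index!r}")
        allowed = _allowed_attributes(self.kind)
        for name in self.attributes:
            if name not in allowed:
                raise ValueError(
                    f"attribute {name!r} not valid for kind {self.kind!r} "
                    f"(allowed: {', '.join(allowed)})")
        # fill omitted canonical attributes with package defaults
        attrs = dict(self.attributes)
        for name in canonical_attributes(self.kind):
            if name not in attrs:
                attrs[name] = ParameterSpec(value=_ATTR_DEFAULTS[name])
        for name, spec in attrs.items():
            if "value" not in spec.model_fields_set:
                default = _ATTR_DEFAULTS.get(name, 0.0)
                lo, hi = spec.min, spec.max
                v = min(max(default, lo), hi)
                object.__setattr__(spec, "value", v)
        object.__setattr__(self, "attributes", attrs)
        return self


class Settings(pydantic.BaseModel):
    """Fit settings; command-line options override these, these override defaults."""

    model_config = pydantic.ConfigDict(extra="allow")

    x_column: Optional[str] = None
    y_column: Optional[Union[str, list[str]]] = None
    energy_shift: float = 0.0
    energy_range: Optional[tuple[float, float]] = None
    method: str = "least_squares"
    method_kwargs: dict[str, Any] = pydantic.Field(default_factory=dict)
    tie_widths: bool = False
    metrics: Optional[list[str]] = None

    @pydantic.field_validator("energy_range")
    @classmethod
    def _range_ok(cls, v):
        if v is not None and not v[0] < v[1]:
            raise ValueError(f"energy_range requires lo < hi, got {v}")
        return v


@dataclass
class FitProject:
    """Validated declarative model: settings + metadata + ordered components."""

    settings: Settings = field(default_factory=Settings)
    description: dict[str, Any] = field(default_factory=dict)
    components: list[ComponentSpec] = field(default_factory=list)
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self):
        if not self.components:
            raise ModelDefinitionError("a fit project needs at least one component")
        seen = set()
        for c in self.components:
            if c.index in seen:
                raise ModelDefinitionError(f"duplicate component index {c.index!r}")
            seen.add(c.index)
        self.components = sorted(self.components, key=lambda c: int(c.index))

    def to_dict(self) -> dict[str, Any]:
        """Serializable document equivalent to the parsed input."""
        peaks: dict[str, Any] = {}
        for c in self.components:
            peaks[c.index] = {c.kind: {
                a: s.model_dump(exclude_none=True) for a, s in c.attributes.items()}}
        doc: dict[str, Any] = dict(self.metadata)
        doc["settings"] = _finite_dict(self.settings.model_dump(exclude_none=True))
        doc["fitting"] = {"description": self.description, "peaks": peaks}
        return doc


def _finite_dict(d):
    """Drop infinite bounds so the document stays TOML/JSON friendly."""
    if isinstance(d, dict):
        return {k: _finite_dict(v) for k, v in d.items()
                if not (isinstance(v, float) and math.isinf(v))}
    if isinstance(d, (list, tuple)):
        return [_finite_dict(v) for v in d]
    return d


_FORMATS = ("json", "yaml", "toml")
_SUFFIX_FORMAT = {".json": "json", ".yaml": "yaml", ".yml": "yaml", ".toml": "toml"}


def _load_document(text: str, fmt: str) -> dict:
    try:
        if fmt == "json":
            return json.loads(text)
        if fmt == "yaml":
            return yaml.safe_load(text)
        if fmt == "toml":
            return tomllib.loads(text)
    except (json.JSONDecodeError, yaml.YAMLError, tomllib.TOMLDecodeError) as exc:
        raise ModelDefinitionError(f"malformed {fmt} document: {exc}") from exc
    raise ModelDefinitionError(f"unknown format {fmt!r}; supported: {_FORMATS}")


def parse_input(source: Union[str, Path], format: Optional[str] = None) -> FitProject:
    """Parse a fit-project document into a :class:`FitProject`.

    ``source`` is a path (format inferred from the suffix unless given)
    or raw document text (format required). The three formats yield
    identical projects for equivalent content. Unknown top-level keys
    are preserved as :attr:`FitProject.metadata`.
    """
    try:
        path = Path(source)
        is_file = path.is_file()
    except (OSError, ValueError):  # raw text can exceed filename limits
        path, is_file = None, False
    if path is not None and is_file and path.suffix.lower() in _SUFFIX_FORMAT:
        fmt = format or _SUFFIX_FORMAT[path.suffix.lower()]
        text = path.read_text()
    elif isinstance(source, Path):
        raise SpectrumError(f"input file not found: {source}")
    else:
        if format is None:
            raise ModelDefinitionError(
                "format must be given ('json', 'yaml', or 'toml') for raw text input")
        fmt, text = format, str(source)
    doc = _load_document(text, fmt)
    if not isinstance(doc, dict):
        raise ModelDefinitionError("input document must be a mapping at top level")
    return _project_from_document(doc)


def _project_from_document(doc: dict) -> FitProject:
    known = {"settings", "fitting"}
    metadata = {k: v for k, v in doc.items() if k not in known}
    try:
        settings = Settings.model_validate(doc.get("settings", {}))
    except pydantic.ValidationError as exc:
        raise ModelDefinitionError(_format_pydantic("settings", exc)) from exc
    fitting = doc.get("fitting", {})
    description = fitting.get("description", {})
    extra_fit = {k: v for k, v in fitting.items() if k not in {"description", "peaks"}}
    if extra_fit:
        metadata.setdefault("fitting_extras", {}).update(extra_fit)
    peaks = fitting.get("peaks", {})
    components = []
    for index, kinds in peaks.items():
        if not isinstance(kinds, dict) or len(kinds) != 1:
            raise ModelDefinitionError(
                f"fitting.peaks.{index} must map exactly one lineshape kind "
                "to its attributes")
        (kind, attrs), = kinds.items()
        try:
            spec = ComponentSpec(index=str(index), kind=kind, attributes=attrs or {})
        except pydantic.ValidationError as exc:
            raise ModelDefinitionError(
                _format_pydantic(f"fitting.peaks.{index}.{kind}", exc)) from exc
        components.append(spec)
    return FitProject(settings=settings, description=description,
                      components=components, metadata=metadata)


def _format_pydantic(prefix: str, exc: pydantic.ValidationError) -> str:
    lines = []
    for err in exc.errors():
        loc = ".".join(str(p) for p in err["loc"])
        where = f"{prefix}.{loc}" if loc else prefix
        lines.append(f"{where}: {err['msg']}")
    return "invalid model definition: " + "; ".join(lines)


def serialize(project: FitProject, format: str = "json") -> str:
    """Render a project back to document text in any supported format."""
    doc = project.to_dict()
    if format == "json":
        return json.dumps(doc, indent=2)
    if format == "yaml":
        return yaml.safe_dump(doc, sort_keys=False)
    if format == "toml":
        from ._toml import dumps
        return dumps(doc)
    raise ModelDefinitionError(f"unknown format {format!r}; supported: {_FORMATS}")


# ---------------------------------------------------------------------------
# spectra

@dataclass
class Spectrum:
    """One spectrum: strictly increasing abscissa + intensity, with labels."""

    x: np.ndarray
    y: np.ndarray
    x_label: str = "energy"
    y_label: str = "intensity"

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.ndim != 1 or self.x.shape != self.y.shape:
            raise SpectrumError(
                f"x and y must be equal-length 1-D vectors, got {self.x.shape} "
                f"and {self.y.shape}")
        if self.x.size == 0:
            raise SpectrumError("empty spectrum")
        if not (np.isfinite(self.x).all() and np.isfinite(self.y).all()):
            raise SpectrumError("spectrum contains non-finite values")
        if self.x.size > 1 and not (np.diff(self.x) > 0).all():
            raise SpectrumError("abscissa must be strictly increasing")

    def __len__(self) -> int:
        return self.x.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({self.x_label: self.x, self.y_label: self.y})


def read_spectrum(path: Union[str, Path], x_column: Optional[str] = None,
                  y_column: Optional[str] = None,
                  sep: Optional[str] = None) -> Spectrum:
    """Read one spectrum from delimited text.

    The delimiter (comma/tab/semicolon/whitespace) is sniffed unless
    ``sep`` is given; a header row is required. Columns default to the
    first (abscissa) and second (intensity) header names. Rows with
    non-numeric cells are dropped with a logged count; a descending
    abscissa is sorted ascending and duplicate abscissa values keep the
    first occurrence (both logged).
    """
    path = Path(path)
    if not path.exists():
        raise SpectrumError(f"data file not found: {path}")
    try:
        frame = pd.read_csv(path, sep=sep, engine="python")
    except Exception as exc:  # pragma: no cover - pandas error wording varies
        raise SpectrumError(f"could not read {path}: {exc}") from exc
    if frame.shape[1] < 2:
        raise SpectrumError(
            f"{path} has {frame.shape[1]} column(s); need an abscissa and an "
            "intensity column")
    x_column = x_column or frame.columns[0]
    y_column = y_column or frame.columns[1]
    for col in (x_column, y_column):
        if col not in frame.columns:
            raise SpectrumError(
                f"column {col!r} not found in {path}; available: "
                f"{', '.join(map(str, frame.columns))}")
    sub = frame[[x_column, y_column]].apply(pd.to_numeric, errors="coerce")
    n_bad = int(sub.isna().any(axis=1).sum())
    if n_bad:
        logger.warning("%s: dropped %d row(s) with non-numeric cells", path, n_bad)
        sub = sub.dropna()
    if sub.empty:
        raise SpectrumError(f"{path}: no numeric rows in columns "
                            f"{x_column!r}/{y_column!r}")
    x = sub[x_column].to_numpy(float)
    y = sub[y_column].to_numpy(float)
    if x.size > 1 and not (np.diff(x) > 0).all():
        order = np.argsort(x, kind="stable")
        if not np.array_equal(order, np.arange(x.size)):
            logger.info("%s: abscissa not ascending; sorted", path)
            x, y = x[order], y[order]
        keep = np.concatenate(([True], np.diff(x) > 0))
        if not keep.all():
            logger.warning("%s: dropped %d duplicate abscissa value(s), kept first",
                           path, int((~keep).sum()))
            x, y = x[keep], y[keep]
    return Spectrum(x=x, y=y, x_label=str(x_column), y_label=str(y_column))


def preprocess(s: Spectrum, shift: float = 0.0,
               range: Optional[tuple[float, float]] = None) -> Spectrum:
    """Shift the abscissa then restrict to a closed range.

    The shift is applied *before* range filtering, so the range bounds
    refer to the shifted axis. Idempotent for shift=0 and a fixed range.
    """
    x = s.x + shift
    y = s.y
    if range is not None:
        lo, hi = range
        if not lo < hi:
            raise InputValidationError(f"range requires lo < hi, got [{lo}, {hi}]")
        mask = (x >= lo) & (x <= hi)
        if not mask.any():
            raise SpectrumError(
                f"no data points remain in range [{lo}, {hi}] after shift {shift}")
        x, y = x[mask], y[mask]
    return Spectrum(x=x, y=y, x_label=s.x_label, y_label=s.y_label)
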