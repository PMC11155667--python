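"""Result persistence: CSV/JSON outputs and the tamper-evident lock file.

A completed fit is saved as three CSVs (fit curve with components,
variables with errors, correlation matrix) plus one JSON holding the
entire fitting project. ``write_lock`` additionally exports a single
TOML document with suffix ``.lock`` whose ``id`` is a SHA-256 over a
canonical rendering (sorted keys, floats at 17 significant digits,
``id``/``timestamp`` excluded), so any change to the input, the data or
the results changes the ID and ``verify_lock`` detects it.
"""

from __future__ import annotations

import datetime as _dt
import hashlib
import json
import math
import tomllib
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Optional, Sequence, Union

import numpy as np
import pandas as pd

from ._toml import dumps as toml_dumps
from .config import FitProject, Spectrum
from .exceptions import LockParseError
from .solver import FitResult
from .statistics import correlation_matrix, regression_metrics, six_tables

__all__ = ["ProjectLock", "write_outputs", "write_lock", "verify_lock",
           "lock_payload", "canonical_form", "content_id"]

SCHEMA_VERSION = 1


@dataclass(frozen=True)
class ProjectLock:
    """In-memory image of a lock document."""

    payload: dict[str, Any]
    id: str
    timestamp: str
    path: Optional[Path] = None


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, dict):
        out = {}
        for k, v in obj.items():
            cv = _jsonable(v)
            if cv is not None:
                out[str(k)] = cv
        return out
    if isinstance(obj, (list, tuple, np.ndarray)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, float) and math.isinf(obj):
        return None  # infinite bounds are implied defaults
    return obj


def _canon(obj: Any) -> Any:
    """Floats to 17-significant-digit strings for a stable hash input."""
    if isinstance(obj, dict):
        return {k: _canon(v) for k, v in obj.items()}
    if isinstance(obj, list):
        return [_canon(v) for v in obj]
    if isinstance(obj, bool):
        return obj
    if isinstance(obj, float):
        return format(obj, ".17g")
    return obj


def canonical_form(payload: dict[str, Any]) -> str:
    """Key-sorted, float-normalized JSON rendering used for hashing."""
    return json.dumps(_canon(_jsonable(payload)), sort_keys=True,
                      separators=(",", ":"))


def content_id(payload: dict[str, Any]) -> str:
    return hashlib.sha256(canonical_form(payload).encode()).hexdigest()


def _result_record(result: FitResult) -> dict[str, Any]:
    rec: dict[str, Any] = {
        "success": bool(result.success),
        "n_eval": int(result.n_eval),
        "best_values": {p.name: p.value for p in result.params},
        "stderr": {p.name: p.stderr for p in result.params
                   if p.stderr is not None},
        "goodness_of_fit": result.gof.as_dict(),
    }
    if result.spectrum is not None:
        reg = regression_metrics(result.spectrum.y, result.model_curve)
        if reg.defined:
            rec["regression_metrics"] = reg.as_dict()
    return rec


def write_outputs(result: FitResult, basename: Union[str, Path],
                  project: Optional[FitProject] = None) -> list[Path]:
    """Write ``<basename>_fit.csv``, ``_errors.csv``, ``_correlation.csv``
    and ``<basename>.json`` for one completed fit."""
    basename = Path(basename)
    basename.parent.mkdir(parents=True, exist_ok=True)
    spectrum = result.spectrum
    if spectrum is None:
        raise ValueError("result carries no spectrum; cannot export")
    tables = six_tables(spectrum, result)

    fit_csv = basename.with_name(basename.name + "_fit.csv")
    frame = pd.DataFrame({spectrum.x_label: spectrum.x,
                          spectrum.y_label: spectrum.y,
                          "fit": result.model_curve,
                          "residual": result.residual,
                          **result.components})
    frame.to_csv(fit_csv, index=False)

    errors_csv = basename.with_name(basename.name + "_errors.csv")
    tables["Variables and Values"].to_csv(errors_csv)

    corr_csv = basename.with_name(basename.name + "_correlation.csv")
    tables["Overall Linear-Correlation"].to_csv(corr_csv)

    json_path = basename.with_name(basename.name + ".json")
    record: dict[str, Any] = {"results": _result_record(result)}
    if project is not None:
        record["input"] = project.to_dict()
    record["data"] = {spectrum.x_label: spectrum.x, spectrum.y_label: spectrum.y}
    json_path.write_text(json.dumps(_jsonable(record), indent=2))
    return [fit_csv, errors_csv, corr_csv, json_path]


def lock_payload(project: FitProject, spectra: Sequence[Spectrum],
                 results: Sequence[FitResult]) -> dict[str, Any]:
    """Everything the lock records (hash input; no id/timestamp)."""
    data = {}
    for i, s in enumerate(spectra, start=1):
        data[f"spectrum_{i}"] = {"x_label": s.x_label, "y_label": s.y_label,
                                 "x": s.x, "y": s.y}
    return _jsonable({
        "schema_version": SCHEMA_VERSION,
        "input": project.to_dict(),
        "data": data,
        "results": {f"fit_{i}": _result_record(r)
                    for i, r in enumerate(results, start=1)},
    })


def write_lock(project: FitProject, spectra: Sequence[Spectrum],
               results: Sequence[FitResult],
               path: Union[str, Path]) -> ProjectLock:
    """Export the single-file TOML lock report with its content-hash ID.

    The ID covers input, data and results but not itself nor the
    timestamp, so re-exports of identical science carry identical IDs.
    """
    path = Path(path)
    if path.suffix != ".lock":
        path = path.with_suffix(path.suffix + ".lock")
    payload = lock_payload(project, spectra, results)
    lock_id = content_id(payload)
    timestamp = _dt.datetime.now(_dt.timezone.utc).isoformat()
    doc = {"id": lock_id, "timestamp": timestamp, **payload}
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(toml_dumps(doc))
    return ProjectLock(payload=payload, id=lock_id, timestamp=timestamp,
                       path=path)


def verify_lock(path: Union[str, Path]) -> dict[str, Any]:
    """Recompute the content hash of a lock file and compare to its ID.

    Returns ``{"valid": bool, "stored_id": ..., "recomputed_id": ...}``.
    A file that does not parse as TOML (or misses the ``id`` field)
    raises :class:`LockParseError` — malformation is distinct from
    tampering.
    """
    path = Path(path)
    try:
        doc = tomllib.loads(path.read_text())
    except (tomllib.TOMLDecodeError, OSError, UnicodeDecodeError) as exc:
        raise LockParseError(f"cannot parse lock file {path}: {exc}") from exc
    if "id" not in doc:
        raise LockParseError(f"lock file {path} has no 'id' field")
    stored = doc["id"]
    payload = {k: v for k, v in doc.items() if k not in {"id", "timestamp"}}
    recomputed = content_id(payload)
    return {"valid": recomputed == stored, "stored_id": stored,
            "recomputed_id": recomputed}
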