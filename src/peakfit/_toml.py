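"""Minimal TOML emitter for the lock/report schema.

Handles the value types the package serializes — mappings, strings,
booleans, integers, floats (including inf/nan), and arrays thereof
(mappings inside arrays become inline tables). Output parses back with
``tomllib``. Scalar keys of a table are written before its sub-tables;
insertion order is preserved so callers control canonical ordering.
"""

from __future__ import annotations

import json
import math
import re
from typing import Any

_BARE_KEY = re.compile(r"^[A-Za-z0-9_-]+$")


def _key(k: str) -> str:
    return k if _BARE_KEY.match(k) else json.dumps(k)


def _scalar(v: Any) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, int):
        return str(v)
    if isinstance(v, float):
        if math.isnan(v):
            return "nan"
        if math.isinf(v):
            return "inf" if v > 0 else "-inf"
        out = repr(v)
        return out if any(c in out for c in ".eE") else out + ".0"
    if isinstance(v, str):
        return json.dumps(v)
    if isinstance(v, (list, tuple)):
        return "[" + ", ".join(_scalar(x) for x in v) + "]"
    if isinstance(v, dict):
        inner = ", ".join(f"{_key(k)} = {_scalar(x)}" for k, x in v.items())
        return "{" + inner + "}"
    raise TypeError(f"cannot serialize {type(v).__name__} to TOML")


def dumps(doc: dict[str, Any]) -> str:
    """Render a mapping as a TOML document string."""
    lines: list[str] = []

    def emit(table: dict[str, Any], path: tuple[str, ...]) -> None:
        scalars = {k: v for k, v in table.items() if not isinstance(v, dict)}
        subtables = {k: v for k, v in table.items() if isinstance(v, dict)}
        if path and (scalars or not subtables):
            lines.append("[" + ".".join(_key(p) for p in path) + "]")
        for k, v in scalars.items():
            lines.append(f"{_key(k)} = {_scalar(v)}")
        if scalars and subtables:
            lines.append("")
        for k, v in subtables.items():
            emit(v, path + (k,))

    emit(doc, ())
    return "\n".join(lines) + "\n"
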