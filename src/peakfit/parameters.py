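"""Flat parameter registry with bounds, vary flags, and constraint expressions.

Parameters are named ``<kind>_<attribute>_<index>`` (for example
``gaussian_amplitude_1``); simultaneous fitting appends a per-spectrum
suffix. A parameter may carry a *constraint expression* instead of being
free: an arithmetic formula over other parameter names, e.g. a constant
branching ratio ``"gaussian_amplitude_1 / 2"``. Expressions are evaluated
in topological order of their dependency graph; cycles are an error.

The expression grammar is a strict whitelist — numbers, parameter names,
``+ - * / **``, unary minus, parentheses, and calls to
``sin, cos, exp, log, sqrt, abs`` — compiled through the Python ``ast``
module with every other construct (attribute access, subscripts,
comprehensions, arbitrary calls, ...) rejected as a security error.
No general code evaluation ever happens.
"""

from __future__ import annotations

import ast
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional

from .config import ComponentSpec
from .exceptions import (ExpressionCycleError, ExpressionError,
                         ExpressionSecurityError, InputValidationError,
                         ModelDefinitionError)

__all__ = ["Parameter", "ParameterSet", "build_names", "resolve_expressions",
           "free_parameters", "compile_expression"]

_ALLOWED_FUNCS = {"sin": math.sin, "cos": math.cos, "exp": math.exp,
                  "log": math.log, "sqrt": math.sqrt, "abs": abs}

_ALLOWED_BINOPS = (ast.Add, ast.Sub, ast.Mult, ast.Div, ast.Pow)
_ALLOWED_UNARY = (ast.USub, ast.UAdd)


@dataclass
class Parameter:
    """One named fit parameter."""

    name: str
    value: float = 0.0
    min: float = -math.inf
    max: float = math.inf
    vary: bool = True
    expr: Optional[str] = None
    stderr: Optional[float] = None
    init_value: Optional[float] = None

    def __post_init__(self):
        if self.expr is not None:
            self.vary = False
        if self.min > self.max:
            raise InputValidationError(
                f"{self.name}: min ({self.min}) > max ({self.max})")
        if self.init_value is None:
            self.init_value = self.value

    @property
    def is_free(self) -> bool:
        return self.vary and self.expr is None


class ParameterSet:
    """Ordered mapping of names to :class:`Parameter` objects."""

    def __init__(self, params: Iterable[Parameter] = ()):
        self._params: dict[str, Parameter] = {}
        for p in params:
            self.add(p)

    def add(self, p: Parameter) -> None:
        if p.name in self._params:
            raise ModelDefinitionError(f"duplicate parameter name {p.name!r}")
        self._params[p.name] = p

    def __getitem__(self, name: str) -> Parameter:
        return self._params[name]

    def __contains__(self, name: str) -> bool:
        return name in self._params

    def __iter__(self):
        return iter(self._params.values())

    def __len__(self) -> int:
        return len(self._params)

    def names(self) -> list[str]:
        return list(self._params)

    def values(self) -> dict[str, float]:
        return {n: p.value for n, p in self._params.items()}

    def copy(self) -> "ParameterSet":
        return ParameterSet(Parameter(**vars(p)) for p in self)


@dataclass(frozen=True)
class CompiledExpression:
    """Validated expression: its AST plus the parameter names it reads."""

    source: str
    tree: ast.Expression
    dependencies: tuple[str, ...] = field(default=())


def compile_expression(source: str) -> CompiledExpression:
    """Parse and validate a constraint expression against the whitelist."""
    try:
        tree = ast.parse(source, mode="eval")
    except SyntaxError as exc:
        raise ExpressionError(f"invalid expression {source!r}: {exc.msg}") from exc
    deps: list[str] = []

    def check(node: ast.AST) -> None:
        if isinstance(node, ast.Expression):
            check(node.body)
        elif isinstance(node, ast.Constant):
            if not isinstance(node.value, (int, float)):
                raise ExpressionSecurityError(
                    f"non-numeric constant in expression {source!r}")
        elif isinstance(node, ast.BinOp) and isinstance(node.op, _ALLOWED_BINOPS):
            check(node.left)
            check(node.right)
        elif isinstance(node, ast.UnaryOp) and isinstance(node.op, _ALLOWED_UNARY):
            check(node.operand)
        elif isinstance(node, ast.Name):
            if node.id not in deps:
                deps.append(node.id)
        elif isinstance(node, ast.Call):
            if not isinstance(node.func, ast.Name) or node.func.id not in _ALLOWED_FUNCS:
                raise ExpressionSecurityError(
                    f"disallowed call in expression {source!r}; allowed functions: "
                    f"{', '.join(sorted(_ALLOWED_FUNCS))}")
            if node.keywords or len(node.args) != 1:
                raise ExpressionSecurityError(
                    f"functions take exactly one positional argument in {source!r}")
            check(node.args[0])
        else:
            raise ExpressionSecurityError(
                f"disallowed construct {type(node).__name__} in expression {source!r}")

    check(tree)
    return CompiledExpression(source=source, tree=tree, dependencies=tuple(deps))


def _eval_compiled(ce: CompiledExpression, env: dict[str, float]) -> float:
    def ev(node: ast.AST) -> float:
        if isinstance(node, ast.Expression):
            return ev(node.body)
        if isinstance(node, ast.Constant):
            return float(node.value)
        if isinstance(node, ast.BinOp):
            a, b = ev(node.left), ev(node.right)
            if isinstance(node.op, ast.Add):
                return a + b
            if isinstance(node.op, ast.Sub):
                return a - b
            if isinstance(node.op, ast.Mult):
                return a * b
            if isinstance(node.op, ast.Div):
                return a / b
            return a**b
        if isinstance(node, ast.UnaryOp):
            v = ev(node.operand)
            return -v if isinstance(node.op, ast.USub) else +v
        if isinstance(node, ast.Name):
            return env[node.id]
        if isinstance(node, ast.Call):
            return _ALLOWED_FUNCS[node.func.id](ev(node.args[0]))
        raise ExpressionError(f"unexpected node {type(node).__name__}")

    try:
        return ev(ce.tree)
    except (ArithmeticError, ValueError) as exc:
        raise ExpressionError(f"expression {ce.source!r} failed: {exc}") from exc


def _dependency_order(ps: ParameterSet) -> list[tuple[Parameter, CompiledExpression]]:
    """Topological order of expression-bound parameters (registry-order ties)."""
    compiled: dict[str, CompiledExpression] = {}
    for p in ps:
        if p.expr is not None:
            ce = compile_expression(p.expr)
            for dep in ce.dependencies:
                if dep not in ps:
                    raise ExpressionError(
                        f"expression for {p.name!r} references unknown parameter "
                        f"{dep!r}")
            compiled[p.name] = ce
    order: list[tuple[Parameter, CompiledExpression]] = []
    state: dict[str, int] = {}  # 0 visiting, 1 done

    def visit(name: str, stack: list[str]) -> None:
        if name not in compiled or state.get(name) == 1:
            return
        if state.get(name) == 0:
            cycle = stack[stack.index(name):] + [name]
            raise ExpressionCycleError(cycle)
        state[name] = 0
        for dep in compiled[name].dependencies:
            visit(dep, stack + [name])
        state[name] = 1
        order.append((ps[name], compiled[name]))

    for name in ps.names():  # deterministic tie-break: registry order
        visit(name, [])
    return order


def resolve_expressions(ps: ParameterSet) -> ParameterSet:
    """Evaluate all constraint expressions in place (topological order).

    Free and fixed parameters are untouched; every expression-bound
    parameter is recomputed from the current values of its dependencies.
    Applying this twice is a no-op (fixed point).
    """
    env = ps.values()
    for p, ce in _dependency_order(ps):
        p.value = _eval_compiled(ce, env)
        env[p.name] = p.value
    return ps


def free_parameters(ps: ParameterSet) -> list[str]:
    """Names of parameters actually optimized, in registry order."""
    return [p.name for p in ps if p.is_free]


def build_names(components: list[ComponentSpec],
                suffix: Optional[str] = None) -> ParameterSet:
    """Construct the flat parameter registry from component specs.

    Names follow ``<kind>_<attribute>_<index>`` plus an optional
    per-spectrum ``_<suffix>`` used by simultaneous fitting.
    """
    if not components:
        raise ModelDefinitionError("cannot build parameters from an empty model")
    ps = ParameterSet()
    for comp in components:
        for attr, spec in comp.attributes.items():
            name = f"{comp.kind}_{attr}_{comp.index}"
            if suffix is not None:
                name = f"{name}_{suffix}"
            ps.add(Parameter(name=name, value=spec.value, min=spec.min,
                             max=spec.max, vary=spec.vary, expr=spec.expr))
    return ps
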