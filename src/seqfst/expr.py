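"""Closed-form differentiable weight expressions.

Transition weights are expression trees over named non-negative parameters,
built from constants, parameter references, the four arithmetic operators,
powers, exponentials and logarithms.  The grammar is deliberately small so
that every expression admits exact symbolic differentiation (needed for
Forward-Backward gradients) and a canonical JSON form (needed for
reproducible serialization).
"""

from __future__ import annotations

import math
from typing import Iterator, Mapping, Union

Number = Union[int, float]
ExprLike = Union["Expr", Number, str]


class UnassignedParameterError(KeyError):
    """A parameter referenced by an expression has no numeric value."""

    def __init__(self, name: str):
        super().__init__(name)
        self.name = name

    def __str__(self) -> str:  # KeyError quotes its arg; keep it readable
        return f"parameter {self.name!r} is not assigned a value"


class WeightDomainError(ValueError):
    """Evaluation produced a negative, NaN or infinite weight."""


def as_expr(value: ExprLike) -> "Expr":
    """Coerce a number, parameter name or Expr into an Expr."""
    if isinstance(value, Expr):
        return value
    if isinstance(value, str):
        return Param(value)
    if isinstance(value, (int, float)):
        return Const(float(value))
    raise TypeError(f"cannot interpret {value!r} as a weight expression")


class Expr:
    """Base class for weight-expression nodes."""

    __slots__ = ()

    def evaluate(self, values: Mapping[str, float]) -> float:
        """Evaluate as a weight: the result must be a finite non-negative real."""
        x = self._eval(values)
        if math.isnan(x) or math.isinf(x) or x < 0:
            raise WeightDomainError(
                f"weight expression evaluated to {x!r}; weights must be "
                "finite and non-negative"
            )
        return x

    def evaluate_signed(self, values: Mapping[str, float]) -> float:
        """Evaluate without the sign restriction (derivatives may be negative)."""
        x = self._eval(values)
        if math.isnan(x) or math.isinf(x):
            raise WeightDomainError(f"expression evaluated to {x!r}")
        return x

    def _eval(self, values: Mapping[str, float]) -> float:
        raise NotImplementedError

    def diff(self, name: str) -> "Expr":
        """Symbolic partial derivative with respect to parameter `name`."""
        raise NotImplementedError

    def params(self) -> set[str]:
        return set(self._params())

    def _params(self) -> Iterator[str]:
        raise NotImplementedError

    def to_json(self):
        raise NotImplementedError

    def monomial(self) -> dict[str, int] | None:
        """Exponent map if the expression is `c * prod(param_i ** k_i)`.

        Returns None for anything richer.  Used by the EM M-step, which is
        closed-form only for monomial weights.
        """
        return None

    # convenience operator sugar -------------------------------------
    def __add__(self, other: ExprLike) -> "Expr":
        return add(self, other)

    def __radd__(self, other: ExprLike) -> "Expr":
        return add(other, self)

    def __mul__(self, other: ExprLike) -> "Expr":
        return mul(self, other)

    def __rmul__(self, other: ExprLike) -> "Expr":
        return mul(other, self)

    def __sub__(self, other: ExprLike) -> "Expr":
        return sub(self, other)

    def __truediv__(self, other: ExprLike) -> "Expr":
        return div(self, other)

    def __eq__(self, other) -> bool:
        return isinstance(other, Expr) and self.to_json() == other.to_json()

    def __hash__(self) -> int:
        return hash(repr(self.to_json()))

    def __repr__(self) -> str:
        return f"{type(self).__name__}({self.to_json()!r})"


class Const(Expr):
    __slots__ = ("value",)

    def __init__(self, value: float):
        # Negative constants are permitted inside derivative expressions;
        # the non-negativity of *weights* is enforced at evaluation time.
        value = float(value)
        if math.isnan(value) or math.isinf(value):
            raise WeightDomainError(f"constant {value!r} is not a finite real")
        self.value = value

    def _eval(self, values):
        return self.value

    def diff(self, name):
        return Const(0.0)

    def _params(self):
        return iter(())

    def to_json(self):
        return self.value

    def monomial(self):
        return {}


class Param(Expr):
    __slots__ = ("name",)

    def __init__(self, name: str):
        if not isinstance(name, str) or not name:
            raise ValueError("parameter name must be a non-empty string")
        self.name = name

    def _eval(self, values):
        try:
            return float(values[self.name])
        except KeyError:
            raise UnassignedParameterError(self.name) from None

    def diff(self, name):
        return Const(1.0 if name == self.name else 0.0)

    def _params(self):
        yield self.name

    def to_json(self):
        return self.name

    def monomial(self):
        return {self.name: 1}


class _Binary(Expr):
    __slots__ = ("left", "right")
    op = ""

    def __init__(self, left: ExprLike, right: ExprLike):
        self.left = as_expr(left)
        self.right = as_expr(right)

    def _params(self):
        yield from self.left._params()
        yield from self.right._params()

    def to_json(self):
        return {self.op: [self.left.to_json(), self.right.to_json()]}


class Add(_Binary):
    op = "+"

    def _eval(self, values):
        return self.left._eval(values) + self.right._eval(values)

    def diff(self, name):
        return add(self.left.diff(name), self.right.diff(name))


class Sub(_Binary):
    op = "-"

    def _eval(self, values):
        return self.left._eval(values) - self.right._eval(values)

    def diff(self, name):
        return sub(self.left.diff(name), self.right.diff(name))


class Mul(_Binary):
    op = "*"

    def _eval(self, values):
        return self.left._eval(values) * self.right._eval(values)

    def diff(self, name):
        return add(mul(self.left.diff(name), self.right),
                   mul(self.left, self.right.diff(name)))

    def monomial(self):
        lm = self.left.monomial()
        rm = self.right.monomial()
        if lm is None or rm is None:
            return None
        out = dict(lm)
        for k, v in rm.items():
            out[k] = out.get(k, 0) + v
        return out


class Div(_Binary):
    op = "/"

    def _eval(self, values):
        return self.left._eval(values) / self.right._eval(values)

    def diff(self, name):
        # (u/v)' = u'/v - u v' / v^2
        return sub(div(self.left.diff(name), self.right),
                   div(mul(self.left, self.right.diff(name)),
                       mul(self.right, self.right)))


class Pow(_Binary):
    op = "pow"

    def _eval(self, values):
        return self.left._eval(values) ** self.right._eval(values)

    def diff(self, name):
        base, expo = self.left, self.right
        if not expo.params():
            # d(u^c) = c * u^(c-1) * u'; keep c symbolic-free
            c = expo._eval({})
            return mul(mul(expo, Pow(base, Const(c - 1.0))), base.diff(name))
        # general: u^v * (v' ln u + v u' / u)
        return mul(self, add(mul(expo.diff(name), Log(base)),
                             div(mul(expo, base.diff(name)), base)))

    def monomial(self):
        bm = self.left.monomial()
        if bm is None or len(bm) != 1 or self.right.params():
            return None
        try:
            k = self.right._eval({})
        except Exception:
            return None
        if k != int(k) or k < 0:
            return None
        (name, e), = bm.items()
        return {name: e * int(k)}


class _Unary(Expr):
    __slots__ = ("arg",)
    op = ""

    def __init__(self, arg: ExprLike):
        self.arg = as_expr(arg)

    def _params(self):
        yield from self.arg._params()

    def to_json(self):
        return {self.op: self.arg.to_json()}


class Exp(_Unary):
    op = "exp"

    def _eval(self, values):
        return math.exp(self.arg._eval(values))

    def diff(self, name):
        return mul(self, self.arg.diff(name))


class Log(_Unary):
    op = "log"

    def _eval(self, values):
        return math.log(self.arg._eval(values))

    def diff(self, name):
        return div(self.arg.diff(name), self.arg)


def _is_const(e: Expr, v: float | None = None) -> bool:
    return isinstance(e, Const) and (v is None or e.value == v)


# smart constructors: fold constants and drop algebraic no-ops so that
# derivatives stay readable and serialized machines stay small
def add(a: ExprLike, b: ExprLike) -> Expr:
    a, b = as_expr(a), as_expr(b)
    if _is_const(a, 0.0):
        return b
    if _is_const(b, 0.0):
        return a
    if isinstance(a, Const) and isinstance(b, Const):
        return Const(a.value + b.value)
    return Add(a, b)


def sub(a: ExprLike, b: ExprLike) -> Expr:
    a, b = as_expr(a), as_expr(b)
    if _is_const(b, 0.0):
        return a
    if isinstance(a, Const) and isinstance(b, Const):
        return Const(a.value - b.value)
    return Sub(a, b)


def mul(a: ExprLike, b: ExprLike) -> Expr:
    a, b = as_expr(a), as_expr(b)
    if _is_const(a, 0.0) or _is_const(b, 0.0):
        return Const(0.0)
    if _is_const(a, 1.0):
        return b
    if _is_const(b, 1.0):
        return a
    if isinstance(a, Const) and isinstance(b, Const):
        return Const(a.value * b.value)
    return Mul(a, b)


def div(a: ExprLike, b: ExprLike) -> Expr:
    a, b = as_expr(a), as_expr(b)
    if _is_const(b, 1.0):
        return a
    if _is_const(a, 0.0):
        return Const(0.0)
    if isinstance(a, Const) and isinstance(b, Const) and b.value != 0:
        return Const(a.value / b.value)
    return Div(a, b)


def power(a: ExprLike, b: ExprLike) -> Expr:
    a, b = as_expr(a), as_expr(b)
    if _is_const(b, 1.0):
        return a
    if _is_const(b, 0.0):
        return Const(1.0)
    if isinstance(a, Const) and isinstance(b, Const):
        return Const(a.value ** b.value)
    return Pow(a, b)


_BINOPS = {"+": add, "-": sub, "*": mul, "/": div, "pow": power}
_UNOPS = {"exp": Exp, "log": Log}
OPERATOR_KEYS = frozenset(_BINOPS) | frozenset(_UNOPS)


def expr_from_json(doc) -> Expr:
    """Parse the JSON weight encoding: number | parameter name | operator object."""
    if isinstance(doc, bool):
        raise ValueError(f"invalid weight {doc!r}")
    if isinstance(doc, (int, float)):
        return Const(float(doc))
    if isinstance(doc, str):
        return Param(doc)
    if isinstance(doc, dict):
        if len(doc) != 1:
            raise ValueError(
                f"weight operator object must have exactly one key, got {sorted(doc)!r}")
        (op, arg), = doc.items()
        if op in _UNOPS:
            return _UNOPS[op](expr_from_json(arg))
        if op in _BINOPS:
            if not isinstance(arg, list) or len(arg) < 2:
                raise ValueError(f"operator {op!r} requires a list of >= 2 operands")
            out = expr_from_json(arg[0])
            for a in arg[1:]:
                out = _BINOPS[op](out, expr_from_json(a))
            return out
        raise ValueError(f"unknown weight operator {op!r}")
    raise ValueError(f"invalid weight {doc!r}")


ONE = Const(1.0)
ZERO = Const(0.0)
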