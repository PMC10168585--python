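"""Scalar parameter functions of growth rate and medium composition.

Every coefficient of an RBA constraint (enzyme efficiency, machine
efficiency, compartment density capacity, target value) is a
:class:`ParameterFunction`: a scalar function of the growth rate ``mu``
and/or the concentration of one external metabolite. Four forms cover the
shapes used in resource-allocation practice:

``constant``
    a fixed value, e.g. an apparent kcat measured at one condition.
``linear_bounded``
    ``clip(intercept + slope * mu, lower_cap, upper_cap)`` — growth-rate
    dependent machine efficiencies and density capacities.
``michaelis_menten``
    ``vmax * c / (c + km)`` in the concentration ``c`` of one external
    metabolite — transporter efficiencies that saturate with substrate.
``product``
    the product of other parameter functions — used for non-destructive
    scaling (screens, knockouts, ensembles).

Functions serialize to a small text grammar, e.g.
``michaelis_menten(vmax=2,km=0.1,arg=glc_ext)`` or
``product(constant(value=2),constant(value=3))``; :func:`parse_parameter`
inverts :func:`serialize_parameter` exactly.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Mapping

__all__ = [
    "ParameterFunction",
    "MissingMediumEntry",
    "ParameterGrammarError",
    "constant",
    "linear_bounded",
    "michaelis_menten",
    "product_of",
    "serialize_parameter",
    "parse_parameter",
]

FORMS = ("constant", "linear_bounded", "michaelis_menten", "product")


class MissingMediumEntry(KeyError):
    """A parameter function references an external metabolite absent from the medium."""


class ParameterGrammarError(ValueError):
    """A serialized parameter string does not follow the documented grammar."""


@dataclass(frozen=True)
class ParameterFunction:
    """A scalar function of growth rate and (optionally) one medium concentration.

    Attributes
    ----------
    form:
        One of ``constant``, ``linear_bounded``, ``michaelis_menten``,
        ``product``.
    coefficients:
        Form-specific named scalars, stored as a sorted tuple of
        ``(name, value)`` pairs so instances hash and compare by value.
    argument:
        For ``michaelis_menten``: the id of the external metabolite whose
        concentration is the function argument. ``None`` otherwise (the
        implicit argument of ``linear_bounded`` is the growth rate).
    operands:
        For ``product``: the factor functions. The empty product is 1.
    """

    form: str
    coefficients: tuple[tuple[str, float], ...] = ()
    argument: str | None = None
    operands: tuple["ParameterFunction", ...] = ()

    def __post_init__(self) -> None:
        if self.form not in FORMS:
            raise ValueError(f"unknown parameter form {self.form!r}")

    def coeff(self, name: str) -> float:
        for key, value in self.coefficients:
            if key == name:
                return value
        raise KeyError(name)

    def __call__(self, mu: float, medium: Mapping[str, float] | None = None) -> float:
        """Evaluate at growth rate ``mu`` under ``medium``.

        Raises
        ------
        MissingMediumEntry
            If a ``michaelis_menten`` form references an external metabolite
            that the medium does not define.
        """
        if self.form == "constant":
            return self.coeff("value")
        if self.form == "linear_bounded":
            raw = self.coeff("intercept") + self.coeff("slope") * mu
            return min(max(raw, self.coeff("lower_cap")), self.coeff("upper_cap"))
        if self.form == "michaelis_menten":
            if medium is None:
                raise MissingMediumEntry(
                    f"parameter needs concentration of {self.argument!r} but no medium was given"
                )
            try:
                conc = medium[self.argument]
            except KeyError:
                raise MissingMediumEntry(
                    f"medium has no entry for external metabolite {self.argument!r}"
                ) from None
            denom = conc + self.coeff("km")
            if denom == 0.0:
                return 0.0
            return self.coeff("vmax") * conc / denom
        # product
        result = 1.0
        for op in self.operands:
            result *= op(mu, medium)
        return result

    def external_metabolites(self) -> set[str]:
        """Ids of external metabolites this function (recursively) depends on."""
        refs: set[str] = set()
        if self.form == "michaelis_menten" and self.argument is not None:
            refs.add(self.argument)
        for op in self.operands:
            refs |= op.external_metabolites()
        return refs


def constant(value: float) -> ParameterFunction:
    return ParameterFunction("constant", (("value", float(value)),))


def linear_bounded(
    intercept: float, slope: float, lower_cap: float, upper_cap: float
) -> ParameterFunction:
    if lower_cap > upper_cap:
        raise ValueError("lower_cap must not exceed upper_cap")
    return ParameterFunction(
        "linear_bounded",
        (
            ("intercept", float(intercept)),
            ("lower_cap", float(lower_cap)),
            ("slope", float(slope)),
            ("upper_cap", float(upper_cap)),
        ),
    )


def michaelis_menten(vmax: float, km: float, metabolite: str) -> ParameterFunction:
    return ParameterFunction(
        "michaelis_menten",
        (("km", float(km)), ("vmax", float(vmax))),
        argument=str(metabolite),
    )


def product_of(*operands: ParameterFunction) -> ParameterFunction:
    return ParameterFunction("product", operands=tuple(operands))


# ---------------------------------------------------------------------------
# Text grammar
#
#   expr     := FORM '(' args ')'
#   args     := kwargs | exprlist | ''
#   kwargs   := NAME '=' (NUMBER | IDENT) (',' kwargs)?     (leaf forms)
#   exprlist := expr (',' expr)?                            (product form)
#
# Floats are serialized with repr() (shortest round-trip form), so
# parse(serialize(f)) == f exactly.
# ---------------------------------------------------------------------------

_ARG_ORDER = {
    "constant": ("value",),
    "linear_bounded": ("intercept", "slope", "lower_cap", "upper_cap"),
    "michaelis_menten": ("vmax", "km"),
}


def serialize_parameter(fn: ParameterFunction) -> str:
    """Render ``fn`` in the text grammar (inverse of :func:`parse_parameter`)."""
    if fn.form == "product":
        inner = ",".join(serialize_parameter(op) for op in fn.operands)
        return f"product({inner})"
    parts = [f"{name}={fn.coeff(name)!r}" for name in _ARG_ORDER[fn.form]]
    if fn.form == "michaelis_menten":
        parts.append(f"arg={fn.argument}")
    return f"{fn.form}({','.join(parts)})"


_NAME_RE = re.compile(r"[A-Za-z_][A-Za-z0-9_]*")


def parse_parameter(text: str) -> ParameterFunction:
    """Parse the grammar produced by :func:`serialize_parameter`."""
    fn, pos = _parse_expr(text, 0)
    if text[pos:].strip():
        raise ParameterGrammarError(f"trailing text at position {pos}: {text[pos:]!r}")
    return fn


def _skip_ws(text: str, pos: int) -> int:
    while pos < len(text) and text[pos].isspace():
        pos += 1
    return pos


def _parse_expr(text: str, pos: int) -> tuple[ParameterFunction, int]:
    pos = _skip_ws(text, pos)
    m = _NAME_RE.match(text, pos)
    if not m:
        raise ParameterGrammarError(f"expected a form name at position {pos} in {text!r}")
    form = m.group(0)
    if form not in FORMS:
        raise ParameterGrammarError(f"unknown parameter form {form!r} in {text!r}")
    pos = _skip_ws(text, m.end())
    if pos >= len(text) or text[pos] != "(":
        raise ParameterGrammarError(f"expected '(' after {form!r} in {text!r}")
    pos += 1
    if form == "product":
        operands: list[ParameterFunction] = []
        pos = _skip_ws(text, pos)
        while pos < len(text) and text[pos] != ")":
            op, pos = _parse_expr(text, pos)
            operands.append(op)
            pos = _skip_ws(text, pos)
            if pos < len(text) and text[pos] == ",":
                pos += 1
        if pos >= len(text):
            raise ParameterGrammarError(f"unterminated product(...) in {text!r}")
        return product_of(*operands), pos + 1
    kwargs: dict[str, str] = {}
    pos = _skip_ws(text, pos)
    while pos < len(text) and text[pos] != ")":
        m = _NAME_RE.match(text, pos)
        if not m:
            raise ParameterGrammarError(f"expected an argument name at position {pos} in {text!r}")
        key = m.group(0)
        pos = _skip_ws(text, m.end())
        if pos >= len(text) or text[pos] != "=":
            raise ParameterGrammarError(f"expected '=' after {key!r} in {text!r}")
        pos = _skip_ws(text, pos + 1)
        end = pos
        while end < len(text) and text[end] not in ",)":
            end += 1
        kwargs[key] = text[pos:end].strip()
        pos = _skip_ws(text, end)
        if pos < len(text) and text[pos] == ",":
            pos = _skip_ws(text, pos + 1)
    if pos >= len(text):
        raise ParameterGrammarError(f"unterminated {form}(...) in {text!r}")
    pos += 1
    try:
        if form == "constant":
            return constant(float(kwargs.pop("value"))), pos
        if form == "linear_bounded":
            return (
                linear_bounded(
                    float(kwargs.pop("intercept")),
                    float(kwargs.pop("slope")),
                    float(kwargs.pop("lower_cap")),
                    float(kwargs.pop("upper_cap")),
                ),
                pos,
            )
        # michaelis_menten
        return (
            michaelis_menten(
                float(kwargs.pop("vmax")), float(kwargs.pop("km")), kwargs.pop("arg")
            ),
            pos,
        )
    except KeyError as exc:
        raise ParameterGrammarError(f"{form} is missing argument {exc} in {text!r}") from None
    except ValueError as exc:
        raise ParameterGrammarError(f"bad numeric literal in {text!r}: {exc}") from None
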