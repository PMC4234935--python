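"""State lists, succ/pred operators, and static expression evaluation.

A site's states form an *ordered* list; the order, not the values, defines
the successor and predecessor operators. On a circular list the last
element connects back to the first. Labels may be integers (consecutive or
not: ``{2,4,6,8,0}`` gives ``succ(2) = 4``) or symbols (``{free, bound,
hidden}`` gives ``succ(free) = bound``); the language attaches no meaning
to the values themselves.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Optional, Tuple, Union

from ._ast import (
    BinOp,
    EnumSpec,
    Expr,
    Name,
    Num,
    RangeSpec,
    SiteAccess,
    SiteDefAST,
    UnaryOp,
)

Label = Union[int, str]


class StaticEvalError(ValueError):
    """Expression is not statically computable (references a non-fixed name)."""


class StateOrderError(ValueError):
    """succ/pred applied at the boundary of a non-circular state list."""


@dataclass(frozen=True)
class StateList:
    """Ordered (optionally circular) labels a site may take."""

    labels: Tuple[Label, ...]
    circular: bool = False

    def __len__(self) -> int:
        return len(self.labels)

    def __contains__(self, s: Label) -> bool:
        return s in self.labels

    def index(self, s: Label) -> int:
        try:
            return self.labels.index(s)
        except ValueError:
            raise StateOrderError(f"state {s!r} is not in the state list {list(self.labels)}")


def successor(states: StateList, s: Label) -> Label:
    """The next label in declaration order; wraps to the first if circular."""
    i = states.index(s)
    if i == len(states.labels) - 1:
        if states.circular:
            return states.labels[0]
        raise StateOrderError(f"the successor of state {s} is not defined")
    return states.labels[i + 1]


def predecessor(states: StateList, s: Label) -> Label:
    """The previous label in declaration order; wraps to the last if circular."""
    i = states.index(s)
    if i == 0:
        if states.circular:
            return states.labels[-1]
        raise StateOrderError(f"the predecessor of state {s} is not defined")
    return states.labels[i - 1]


def apply_op(op: Optional[str], states: StateList, s: Label) -> Label:
    if op is None:
        return s
    if op == "succ":
        return successor(states, s)
    if op == "pred":
        return predecessor(states, s)
    raise ValueError(f"unknown state operator {op!r}")


# ---------------------------------------------------------------------------
# Static evaluation
# ---------------------------------------------------------------------------

def eval_number(
    expr: Expr,
    globals_env: Optional[Dict[str, object]] = None,
    site_env: Optional[Dict[Tuple[str, str], int]] = None,
    _active: Optional[frozenset] = None,
) -> float:
    """Evaluate *expr* to a number using fixed global quantities only.

    ``globals_env`` maps names to GlobalQuantity-like objects (``role``,
    ``initial_expr`` attributes) or plain numbers. ``site_env`` optionally
    supplies integer values for ``species.site`` accessors (used when
    grounding instance-dependent bounds during expansion). Raises
    :class:`StaticEvalError` on any other reference.
    """
    genv = globals_env or {}
    active = _active or frozenset()
    if isinstance(expr, Num):
        return float(expr.value)
    if isinstance(expr, Name):
        if expr.ident not in genv:
            raise StaticEvalError(f"{expr.ident!r} is not a statically computable quantity")
        target = genv[expr.ident]
        if isinstance(target, (int, float)):
            return float(target)
        if getattr(target, "role", "fixed") != "fixed":
            raise StaticEvalError(
                f"{expr.ident!r} is an assigned quantity and cannot parameterize a range"
            )
        if expr.ident in active:
            raise StaticEvalError(f"circular definition of global quantity {expr.ident!r}")
        return eval_number(
            target.initial_expr, genv, site_env, active | {expr.ident}
        )
    if isinstance(expr, SiteAccess):
        if site_env is not None and (expr.species, expr.site) in site_env:
            return float(site_env[(expr.species, expr.site)])
        raise StaticEvalError(
            f"site accessor {expr.species}.{expr.site} has no value in this context"
        )
    if isinstance(expr, UnaryOp):
        return -eval_number(expr.operand, genv, site_env, active)
    if isinstance(expr, BinOp):
        a = eval_number(expr.left, genv, site_env, active)
        b = eval_number(expr.right, genv, site_env, active)
        if expr.op == "+":
            return a + b
        if expr.op == "-":
            return a - b
        if expr.op == "*":
            return a * b
        if expr.op == "/":
            return a / b
        if expr.op == "^":
            return a**b
        raise StaticEvalError(f"unknown operator {expr.op!r}")
    raise StaticEvalError(
        f"{type(expr).__name__} is not allowed in a statically computable expression"
    )


def evaluate_static(
    expr: Expr,
    globals_env: Optional[Dict[str, object]] = None,
    site_env: Optional[Dict[Tuple[str, str], int]] = None,
) -> int:
    """Evaluate to an integer for use as a range bound or state value.

    Non-integer results are rounded down (``7.8`` -> ``7``).
    """
    return math.floor(eval_number(expr, globals_env, site_env))


def resolve_state_list(
    site: SiteDefAST, globals_env: Optional[Dict[str, object]] = None
) -> StateList:
    """Resolve a site definition to its concrete ordered state list.

    Integer ranges are inclusive on both ends (``{0:10}`` has 11 states);
    symbolic bounds are evaluated over fixed global quantities, flooring
    non-integer values. An inverted range (lo > hi) resolves to an empty
    list (the caller reports the empty-range warning). An open site (no
    state list, e.g. an assigned modifier species) resolves to an empty,
    non-circular list.
    """
    if site.states is None:
        return StateList((), circular=site.circular)
    if isinstance(site.states, EnumSpec):
        return StateList(tuple(site.states.labels), circular=site.circular)
    if isinstance(site.states, RangeSpec):
        lo = evaluate_static(site.states.lo, globals_env)
        hi = evaluate_static(site.states.hi, globals_env)
        return StateList(tuple(range(lo, hi + 1)), circular=site.circular)
    raise TypeError(f"unknown state spec {type(site.states).__name__}")
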