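"""Abstract syntax tree for the multistate model language.

Every node carries a source location (line, column) that is excluded from
structural equality, so ``parse(unparse(parse(text)))`` compares equal to
``parse(text)`` even though the two trees originate from different text.

Expression nodes form an ordinary arithmetic tree plus two domain
constructs: ``SiteAccess`` (``species.site`` — the state value of a site,
resolved per expanded instance) and ``SumNode`` (the SUM aggregate over a
species' states, optionally restricted per site and weighted per term).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple, Union

Loc = Optional[Tuple[int, int]]


def _loc_field() -> Loc:
    return field(default=None, compare=False, repr=False)  # type: ignore[return-value]


# ---------------------------------------------------------------------------
# Expressions
# ---------------------------------------------------------------------------

@dataclass
class Num:
    value: float
    loc: Loc = _loc_field()


@dataclass
class Name:
    ident: str
    loc: Loc = _loc_field()


@dataclass
class SiteAccess:
    """``species.site`` — the numeric/label state of a site in context."""

    species: str
    site: str
    loc: Loc = _loc_field()


@dataclass
class BinOp:
    op: str  # one of + - * / ^
    left: "Expr"
    right: "Expr"
    loc: Loc = _loc_field()


@dataclass
class UnaryOp:
    op: str  # '-'
    operand: "Expr"
    loc: Loc = _loc_field()


@dataclass
class Call:
    func: str
    args: List["Expr"]
    loc: Loc = _loc_field()


@dataclass
class RangeExpr:
    """Inclusive lo:hi over a site's states; both None means the full list."""

    lo: Optional["Expr"]
    hi: Optional["Expr"]
    loc: Loc = _loc_field()


@dataclass
class SumNode:
    """SUM(species; site{lo:hi}; ...; weight?)."""

    species: str
    restrictions: List[Tuple[str, RangeExpr]]
    weight: Optional["Expr"] = None
    loc: Loc = _loc_field()


Expr = Union[Num, Name, SiteAccess, BinOp, UnaryOp, Call, SumNode]


# ---------------------------------------------------------------------------
# Species definitions
# ---------------------------------------------------------------------------

@dataclass
class RangeSpec:
    """Integer range of states, bounds are static arithmetic expressions."""

    lo: Expr
    hi: Expr
    loc: Loc = _loc_field()


@dataclass
class EnumSpec:
    """Explicitly enumerated, ordered state labels (ints or symbols)."""

    labels: List[Union[int, str]]
    loc: Loc = _loc_field()


@dataclass
class SiteDefAST:
    name: str
    states: Optional[Union[RangeSpec, EnumSpec]]  # None: open site (no states)
    circular: bool = False
    loc: Loc = _loc_field()


@dataclass
class SpeciesDefAST:
    name: str
    sites: List[SiteDefAST]
    default_initial: Optional[Expr] = None
    assignment: Optional[Expr] = None  # ':=' assigned species (e.g. modifiers)
    loc: Loc = _loc_field()


# ---------------------------------------------------------------------------
# Species references (patterns) inside reactions
# ---------------------------------------------------------------------------

@dataclass
class FixedState:
    """Single admitted state; an expression (number, label or global)."""

    value: Expr
    loc: Loc = _loc_field()


@dataclass
class RangePattern:
    """lo:hi admitted range; (None, None) = explicit full-range mention."""

    lo: Optional[Expr]
    hi: Optional[Expr]
    loc: Loc = _loc_field()


@dataclass
class OpCall:
    """succ(site) / pred(site) — state derived from the matched reactant."""

    op: str  # 'succ' | 'pred'
    site: str
    loc: Loc = _loc_field()


@dataclass
class Transfer:
    """site = [succ|pred] source_species.source_site (transfer of state)."""

    source_species: str
    source_site: str
    op: Optional[str] = None  # None | 'succ' | 'pred'
    loc: Loc = _loc_field()


Pattern = Union[FixedState, RangePattern, OpCall, Transfer]


@dataclass
class SpeciesRefAST:
    species: str
    site_patterns: List[Tuple[str, Pattern]]
    loc: Loc = _loc_field()

    def pattern_for(self, site: str) -> Optional[Pattern]:
        for name, pat in self.site_patterns:
            if name == site:
                return pat
        return None


# ---------------------------------------------------------------------------
# Reactions, globals, functions, complexes, initials
# ---------------------------------------------------------------------------

@dataclass
class MassActionLaw:
    rate: Expr  # rate-constant expression (usually a global name)
    loc: Loc = _loc_field()


@dataclass
class UserDefinedLaw:
    func: str
    args: List[Expr]
    loc: Loc = _loc_field()


@dataclass
class RawKineticLaw:
    """Explicit kinetic expression (used by the flat single-state dialect)."""

    expr: "Expr"
    loc: Loc = _loc_field()


RateLaw = Union[MassActionLaw, UserDefinedLaw, RawKineticLaw]


@dataclass
class ReactionAST:
    reactants: List[SpeciesRefAST]
    products: List[SpeciesRefAST]
    modifiers: List[SpeciesRefAST]
    rate_law: Optional[RateLaw] = None
    loc: Loc = _loc_field()


@dataclass
class GlobalQuantityAST:
    name: str
    role: str  # 'fixed' | 'assigned'
    initial_expr: Expr
    loc: Loc = _loc_field()


@dataclass
class FunctionDefAST:
    name: str
    params: List[Tuple[str, str]]  # (name, role in {GLQ, SITE, SUB})
    body: Expr
    loc: Loc = _loc_field()


@dataclass
class ComplexComponentAST:
    species: str
    # tracked sites: (site name, optional restriction range); empty list =
    # untracked component (or zero-site species)
    tracked: List[Tuple[str, Optional[RangeExpr]]]
    loc: Loc = _loc_field()


@dataclass
class ComplexDefAST:
    name: Optional[str]  # None -> auto-named from components
    components: List[ComplexComponentAST]
    generate_reactions: bool = False
    loc: Loc = _loc_field()


@dataclass
class StateInitialAST:
    """Per-state initial value: Species(s1{a}, s2{b}) = amount."""

    species: str
    assignment: List[Tuple[str, Union[int, str]]]
    value: Expr
    loc: Loc = _loc_field()


@dataclass
class ModelAST:
    species: List[SpeciesDefAST] = field(default_factory=list)
    reactions: List[ReactionAST] = field(default_factory=list)
    globals: List[GlobalQuantityAST] = field(default_factory=list)
    functions: List[FunctionDefAST] = field(default_factory=list)
    complexes: List[ComplexDefAST] = field(default_factory=list)
    initials: List[StateInitialAST] = field(default_factory=list)
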