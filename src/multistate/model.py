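"""Semantic model: name resolution, validation, refactoring, complexes.

The model is deliberately permissive: every inconsistency becomes a
:class:`~multistate.issues.ValidationIssue` rather than an exception, and
a model carrying issues of any severity can still be serialized to text
and read back losslessly. Only the expander (see :mod:`multistate.expand`)
refuses to work on a model with outstanding error-severity issues.
"""
from __future__ import annotations

import copy
import re
from dataclasses import dataclass, field as dc_field
from typing import Dict, Iterable, List, Optional, Tuple, Union

from ._ast import (
    BinOp,
    Call,
    ComplexComponentAST,
    ComplexDefAST,
    EnumSpec,
    Expr,
    FixedState,
    FunctionDefAST,
    GlobalQuantityAST,
    MassActionLaw,
    ModelAST,
    Name,
    Num,
    OpCall,
    Pattern,
    RangeExpr,
    RangePattern,
    RangeSpec,
    RawKineticLaw,
    ReactionAST,
    SiteAccess,
    SiteDefAST,
    SpeciesDefAST,
    SpeciesRefAST,
    StateInitialAST,
    SumNode,
    Transfer,
    UnaryOp,
    UserDefinedLaw,
)
from .issues import Severity, ValidationIssue
from .states import (
    Label,
    StateList,
    StateOrderError,
    StaticEvalError,
    apply_op,
    evaluate_static,
    resolve_state_list,
)
from .unparse import unparse

_IDENT_RE = re.compile(r"^[A-Za-z0-9_]+$")


def is_legal_identifier(name: str) -> bool:
    """Letters, digits, underscore; a leading digit is allowed as long as
    the name is not a pure number (``80S`` is legal, ``80`` is not)."""
    return bool(_IDENT_RE.match(name)) and not name.isdigit()


# ---------------------------------------------------------------------------
# Preferences (the "Preferences menu" as a config object / key=value file)
# ---------------------------------------------------------------------------

@dataclass
class Preferences:
    autocompletion_policy: str = "silent"  # off | confirm | silent
    default_initial: float = 0.0
    default_delete_policy: str = "cascade"  # cascade | leave_dangling

    @classmethod
    def from_file(cls, path) -> "Preferences":
        prefs = cls()
        with open(path, "r", encoding="utf-8") as fh:
            for raw in fh:
                line = raw.split("#", 1)[0].strip()
                if not line:
                    continue
                key, _, value = line.partition("=")
                key = key.strip()
                value = value.strip()
                if key == "autocompletion_policy":
                    prefs.autocompletion_policy = value
                elif key == "default_initial":
                    prefs.default_initial = float(value)
                elif key == "default_delete_policy":
                    prefs.default_delete_policy = value
        return prefs


# ---------------------------------------------------------------------------
# Semantic entities
# ---------------------------------------------------------------------------

@dataclass
class MultistateSpecies:
    """A species with 0..n sites, each carrying an ordered state list.

    ``per_state_initials`` maps a full state assignment — one label per
    site, in site declaration order — to an amount expression; unlisted
    states inherit ``default_initial``.
    """

    name: str
    sites: List[SiteDefAST] = dc_field(default_factory=list)
    default_initial: Optional[Expr] = None
    assignment: Optional[Expr] = None
    per_state_initials: Dict[Tuple[Label, ...], Expr] = dc_field(default_factory=dict)
    origin_complex: Optional[str] = None
    auto_created: bool = False

    def site(self, name: str) -> Optional[SiteDefAST]:
        for s in self.sites:
            if s.name == name:
                return s
        return None

    @property
    def is_multistate(self) -> bool:
        return bool(self.sites)


@dataclass
class GlobalQuantity:
    name: str
    role: str  # fixed | assigned
    initial_expr: Expr


@dataclass
class FunctionDef:
    name: str
    params: List[Tuple[str, str]]  # (name, role)
    body: Expr


@dataclass
class MultistateReaction(ReactionAST):
    origin_complex: Optional[str] = None


@dataclass
class ComplexSpecies:
    name: str
    components: List[ComplexComponentAST]
    generate_reactions: bool = False
    auto_named: bool = False
    # complex site name -> (component species, component site)
    site_map: Dict[str, Tuple[str, str]] = dc_field(default_factory=dict)


class Model:
    """A (possibly inconsistent) multistate model."""

    def __init__(self, preferences: Optional[Preferences] = None):
        self.preferences = preferences or Preferences()
        self.species: Dict[str, MultistateSpecies] = {}
        self.reactions: List[MultistateReaction] = []
        self.globals: Dict[str, GlobalQuantity] = {}
        self.functions: Dict[str, FunctionDef] = {}
        self.complexes: Dict[str, ComplexSpecies] = {}
        self.pending_species: List[str] = []  # autocompletion policy 'confirm'

    # -- convenience -------------------------------------------------------
    def global_env(self) -> Dict[str, GlobalQuantity]:
        return self.globals

    def state_list(self, species: str, site: str) -> StateList:
        sp = self.species[species]
        sd = sp.site(site)
        if sd is None:
            raise KeyError(f"{species} has no site {site!r}")
        return resolve_state_list(sd, self.globals)

    def copy(self) -> "Model":
        return copy.deepcopy(self)

    # -- serialization -----------------------------------------------------
    def to_ast(self) -> ModelAST:
        ast = ModelAST()
        for sp in self.species.values():
            if sp.origin_complex is not None:
                continue
            ast.species.append(
                SpeciesDefAST(sp.name, sp.sites, sp.default_initial, sp.assignment)
            )
        for rxn in self.reactions:
            if rxn.origin_complex is not None:
                continue
            ast.reactions.append(
                ReactionAST(rxn.reactants, rxn.products, rxn.modifiers, rxn.rate_law)
            )
        for g in self.globals.values():
            ast.globals.append(GlobalQuantityAST(g.name, g.role, g.initial_expr))
        for f in self.functions.values():
            ast.functions.append(FunctionDefAST(f.name, f.params, f.body))
        for c in self.complexes.values():
            ast.complexes.append(
                ComplexDefAST(
                    None if c.auto_named else c.name, c.components, c.generate_reactions
                )
            )
        for sp in self.species.values():
            site_names = [s.name for s in sp.sites]
            for key, value in sp.per_state_initials.items():
                ast.initials.append(
                    StateInitialAST(sp.name, list(zip(site_names, key)), value)
                )
        return ast

    def to_msl(self) -> str:
        return unparse(self.to_ast())


# ---------------------------------------------------------------------------
# Expression walking helpers
# ---------------------------------------------------------------------------

def iter_names(expr: Expr) -> Iterable[Tuple[str, Expr]]:
    """Yield (kind, node) for every reference inside an expression tree.

    Kinds: ``name`` (bare identifier), ``site`` (species.site accessor),
    ``call`` (function call), ``sum`` (SUM aggregate).
    """
    stack = [expr]
    while stack:
        node = stack.pop()
        if isinstance(node, Name):
            yield ("name", node)
        elif isinstance(node, SiteAccess):
            yield ("site", node)
        elif isinstance(node, UnaryOp):
            stack.append(node.operand)
        elif isinstance(node, BinOp):
            stack.extend((node.left, node.right))
        elif isinstance(node, Call):
            yield ("call", node)
            stack.extend(node.args)
        elif isinstance(node, SumNode):
            yield ("sum", node)
            for _, r in node.restrictions:
                if r.lo is not None:
                    stack.append(r.lo)
                if r.hi is not None and r.hi is not r.lo:
                    stack.append(r.hi)
            if node.weight is not None:
                stack.append(node.weight)


def substitute_name(expr: Expr, name: str, replacement: Expr) -> Expr:
    """Return *expr* with every bare reference to *name* replaced."""
    if isinstance(expr, Name):
        return copy.deepcopy(replacement) if expr.ident == name else expr
    if isinstance(expr, UnaryOp):
        return UnaryOp(expr.op, substitute_name(expr.operand, name, replacement), loc=expr.loc)
    if isinstance(expr, BinOp):
        return BinOp(
            expr.op,
            substitute_name(expr.left, name, replacement),
            substitute_name(expr.right, name, replacement),
            loc=expr.loc,
        )
    if isinstance(expr, Call):
        return Call(
            expr.func, [substitute_name(a, name, replacement) for a in expr.args], loc=expr.loc
        )
    if isinstance(expr, SumNode):
        restr = []
        for site, r in expr.restrictions:
            lo = substitute_name(r.lo, name, replacement) if r.lo is not None else None
            hi = substitute_name(r.hi, name, replacement) if r.hi is not None else None
            restr.append((site, RangeExpr(lo, hi, loc=r.loc)))
        weight = (
            substitute_name(expr.weight, name, replacement) if expr.weight is not None else None
        )
        return SumNode(expr.species, restr, weight, loc=expr.loc)
    return expr


# ---------------------------------------------------------------------------
# build_model
# ---------------------------------------------------------------------------

def build_model(
    ast: ModelAST,
    autocompletion_policy: Optional[str] = None,
    preferences: Optional[Preferences] = None,
) -> Tuple[Model, List[ValidationIssue]]:
    """Resolve an AST into a :class:`Model`.

    Species referenced in reactions but never defined are handled per the
    autocompletion policy: ``silent`` creates them (with the configured
    default initial amount) and records a warning; ``off`` leaves them
    undefined and records an error; ``confirm`` records them in
    ``model.pending_species`` for the caller to resolve. The model is
    returned in every case — nothing here is fatal.
    """
    prefs = preferences or Preferences()
    policy = autocompletion_policy or prefs.autocompletion_policy
    model = Model(prefs)
    issues: List[ValidationIssue] = []

    def dup(kind: str, name: str, loc) -> None:
        issues.append(
            ValidationIssue(
                Severity.ERROR, "duplicate-definition", f"{kind} {name!r} defined twice", loc
            )
        )

    for sp in ast.species:
        if sp.name in model.species:
            dup("species", sp.name, sp.loc)
            continue
        model.species[sp.name] = MultistateSpecies(
            sp.name, sp.sites, sp.default_initial, sp.assignment
        )
    for g in ast.globals:
        if g.name in model.globals:
            dup("global quantity", g.name, g.loc)
            continue
        model.globals[g.name] = GlobalQuantity(g.name, g.role, g.initial_expr)
    for f in ast.functions:
        if f.name in model.functions:
            dup("function", f.name, f.loc)
            continue
        model.functions[f.name] = FunctionDef(f.name, f.params, f.body)
    for rxn in ast.reactions:
        model.reactions.append(
            MultistateReaction(rxn.reactants, rxn.products, rxn.modifiers, rxn.rate_law, rxn.loc)
        )
    for c in ast.complexes:
        try:
            build_complex(
                model,
                c.components,
                name=c.name,
                generate_reactions=c.generate_reactions,
            )
        except ValueError as exc:
            issues.append(
                ValidationIssue(Severity.ERROR, "bad-complex", str(exc), c.loc)
            )
    for init in ast.initials:
        sp = model.species.get(init.species)
        if sp is None:
            issues.append(
                ValidationIssue(
                    Severity.ERROR,
                    "undef-species",
                    f"per-state initial for undefined species {init.species!r}",
                    init.loc,
                )
            )
            continue
        site_names = [s.name for s in sp.sites]
        given = dict(init.assignment)
        if sorted(given) != sorted(site_names):
            issues.append(
                ValidationIssue(
                    Severity.ERROR,
                    "bad-initial",
                    f"per-state initial for {init.species!r} must assign every site "
                    f"exactly once (sites: {site_names})",
                    init.loc,
                )
            )
            continue
        key = tuple(given[s] for s in site_names)
        sp.per_state_initials[key] = init.value

    # autocompletion of species referenced in reactions
    for rxn in model.reactions:
        for ref in rxn.reactants + rxn.products + rxn.modifiers:
            if ref.species in model.species:
                continue
            if policy == "silent":
                model.species[ref.species] = MultistateSpecies(
                    ref.species,
                    default_initial=Num(prefs.default_initial),
                    auto_created=True,
                )
                issues.append(
                    ValidationIssue(
                        Severity.WARNING,
                        "auto-created",
                        f"species {ref.species!r} was not defined; created with "
                        f"default initial amount {prefs.default_initial}",
                        ref.loc,
                    )
                )
            elif policy == "off":
                issues.append(
                    ValidationIssue(
                        Severity.ERROR,
                        "undef-species",
                        f"species {ref.species!r} is used in a reaction but never defined",
                        ref.loc,
                    )
                )
            elif policy == "confirm":
                if ref.species not in model.pending_species:
                    model.pending_species.append(ref.species)
                    issues.append(
                        ValidationIssue(
                            Severity.INFO,
                            "pending-species",
                            f"species {ref.species!r} awaits confirmation before "
                            "being auto-created",
                            ref.loc,
                        )
                    )
            else:
                raise ValueError(f"unknown autocompletion policy {policy!r}")
    return model, issues


def confirm_pending(model: Model) -> List[ValidationIssue]:
    """Create every pending species (autocompletion policy ``confirm``)."""
    issues = []
    for name in model.pending_species:
        if name not in model.species:
            model.species[name] = MultistateSpecies(
                name,
                default_initial=Num(model.preferences.default_initial),
                auto_created=True,
            )
            issues.append(
                ValidationIssue(
                    Severity.WARNING, "auto-created", f"species {name!r} auto-created", None
                )
            )
    model.pending_species.clear()
    return issues


# ---------------------------------------------------------------------------
# Pattern admission (shared with the expander)
# ---------------------------------------------------------------------------

def admitted_labels(
    pattern: Optional[Pattern], states: StateList, globals_env
) -> List[Label]:
    """The state labels a reactant-side pattern admits.

    No pattern / a bare site mention admits the full list. A range over
    integer labels selects by numeric value; over symbolic labels it
    selects the positional span between the two named labels. A fixed
    state admits its single label (resolved through fixed globals when it
    is not literally a label).
    """
    if pattern is None:
        return list(states.labels)
    if isinstance(pattern, RangePattern):
        if pattern.lo is None and pattern.hi is None:
            return list(states.labels)
        return _labels_in_range(pattern.lo, pattern.hi, states, globals_env)
    if isinstance(pattern, FixedState):
        label = resolve_fixed(pattern.value, states, globals_env)
        return [label]
    raise ValueError(f"{type(pattern).__name__} is not a reactant-side pattern")


def _labels_in_range(lo_expr, hi_expr, states: StateList, globals_env) -> List[Label]:
    # symbolic positional span: both bounds are labels of a symbolic list
    if isinstance(lo_expr, Name) and lo_expr.ident in states.labels:
        if isinstance(hi_expr, Name) and hi_expr.ident in states.labels:
            i = states.labels.index(lo_expr.ident)
            j = states.labels.index(hi_expr.ident)
            return list(states.labels[i : j + 1])
    lo = evaluate_static(lo_expr, globals_env)
    hi = evaluate_static(hi_expr, globals_env)
    return [s for s in states.labels if isinstance(s, int) and lo <= s <= hi]


def resolve_fixed(value_expr: Expr, states: StateList, globals_env) -> Label:
    """Resolve a fixed-state pattern value to a label of the state list."""
    if isinstance(value_expr, Name) and value_expr.ident in states.labels:
        return value_expr.ident
    label = evaluate_static(value_expr, globals_env)
    if label not in states.labels:
        raise StateOrderError(
            f"state {label} is not in the state list {list(states.labels)}"
        )
    return label


# ---------------------------------------------------------------------------
# validate
# ---------------------------------------------------------------------------

def validate(model: Model) -> List[ValidationIssue]:
    """Run every consistency check; diagnostics only, never mutates.

    Checks: operator range coherence (succ of the last state / pred of the
    first on non-circular sites), transfer compatibility, static
    computability of range bounds, undefined identifiers in expressions,
    function-call arity and parameter roles, SUM restrictions against the
    species' state lists, pattern/site existence, determinability of every
    product state, and complex component restrictions.
    """
    issues: List[ValidationIssue] = []
    genv = model.globals

    def err(code: str, msg: str, loc=None) -> None:
        issues.append(ValidationIssue(Severity.ERROR, code, msg, loc))

    def warn(code: str, msg: str, loc=None) -> None:
        issues.append(ValidationIssue(Severity.WARNING, code, msg, loc))

    def check_expr(expr: Expr, loc=None, context: str = "") -> None:
        for kind, node in iter_names(expr):
            where = f" in {context}" if context else ""
            if kind == "name":
                if node.ident not in genv and node.ident not in model.species:
                    err(
                        "undef-identifier",
                        f"{node.ident!r} is not defined{where}",
                        node.loc or loc,
                    )
            elif kind == "site":
                sp = model.species.get(node.species)
                if sp is None:
                    err(
                        "undef-species",
                        f"species {node.species!r} is not defined{where}",
                        node.loc or loc,
                    )
                elif sp.site(node.site) is None:
                    err(
                        "undef-site",
                        f"species {node.species!r} has no site {node.site!r}{where}",
                        node.loc or loc,
                    )
            elif kind == "call":
                fn = model.functions.get(node.func)
                if fn is None:
                    err(
                        "undef-identifier",
                        f"function {node.func!r} is not defined{where}",
                        node.loc or loc,
                    )
                elif len(node.args) != len(fn.params):
                    err(
                        "func-arity",
                        f"function {node.func!r} takes {len(fn.params)} arguments, "
                        f"got {len(node.args)}{where}",
                        node.loc or loc,
                    )
            elif kind == "sum":
                _check_sum(node, loc, context)

    def _check_sum(node: SumNode, loc, context) -> None:
        sp = model.species.get(node.species)
        where = f" in {context}" if context else ""
        if sp is None:
            err(
                "undef-species",
                f"SUM over undefined species {node.species!r}{where}",
                node.loc or loc,
            )
            return
        seen = set()
        for site_name, r in node.restrictions:
            if site_name in seen:
                err(
                    "duplicate-restriction",
                    f"SUM restricts site {site_name!r} twice{where}",
                    node.loc or loc,
                )
            seen.add(site_name)
            sd = sp.site(site_name)
            if sd is None:
                err(
                    "undef-site",
                    f"SUM over {node.species!r}: no site {site_name!r}{where}",
                    node.loc or loc,
                )
                continue
            # static bounds must stay inside the state list; bounds that
            # depend on an instance site value are checked at expansion
            try:
                states = resolve_state_list(sd, genv)
                labels = _labels_in_range(r.lo, r.hi, states, genv)
                lo = evaluate_static(r.lo, genv)
                hi = evaluate_static(r.hi, genv)
                numeric = [s for s in states.labels if isinstance(s, int)]
                if numeric and (lo < min(numeric) or hi > max(numeric)):
                    err(
                        "sum-out-of-range",
                        f"SUM restriction {site_name}{{{lo}:{hi}}} exceeds the state "
                        f"list of {node.species}.{site_name}{where}",
                        node.loc or loc,
                    )
                elif not labels:
                    warn(
                        "empty-range",
                        f"SUM restriction on {node.species}.{site_name} admits no "
                        f"states{where}",
                        node.loc or loc,
                    )
            except StaticEvalError:
                pass  # instance-dependent bound (e.g. M.c+1): expansion-time check

    # species definitions -------------------------------------------------
    for sp in model.species.values():
        for sd in sp.sites:
            if isinstance(sd.states, RangeSpec):
                try:
                    states = resolve_state_list(sd, genv)
                    if len(states) == 0:
                        warn(
                            "empty-range",
                            f"site {sp.name}.{sd.name} has an empty state range",
                            sd.loc,
                        )
                except StaticEvalError as exc:
                    err("non-static-range", f"site {sp.name}.{sd.name}: {exc}", sd.loc)
        if sp.default_initial is not None:
            check_expr(sp.default_initial, context=f"initial amount of {sp.name!r}")
        if sp.assignment is not None:
            check_expr(sp.assignment, context=f"assignment of {sp.name!r}")
        for value in sp.per_state_initials.values():
            check_expr(value, context=f"per-state initial of {sp.name!r}")

    # global quantities ----------------------------------------------------
    for g in model.globals.values():
        check_expr(g.initial_expr, context=f"global quantity {g.name!r}")

    # function bodies: every identifier must be a parameter ----------------
    for fn in model.functions.values():
        params = {p for p, _ in fn.params}
        for kind, node in iter_names(fn.body):
            if kind == "name" and node.ident not in params:
                err(
                    "undef-identifier",
                    f"function {fn.name!r} body references {node.ident!r} which is "
                    "not a parameter",
                    node.loc,
                )

    # reactions ------------------------------------------------------------
    for idx, rxn in enumerate(model.reactions):
        _validate_reaction(model, idx, rxn, issues, err, warn, check_expr)

    # complexes ------------------------------------------------------------
    for cx in model.complexes.values():
        for comp in cx.components:
            sp = model.species.get(comp.species)
            if sp is None:
                err(
                    "undef-species",
                    f"complex {cx.name!r}: component {comp.species!r} is not defined",
                    comp.loc,
                )
                continue
            for site_name, r in comp.tracked:
                if sp.site(site_name) is None:
                    err(
                        "undef-site",
                        f"complex {cx.name!r}: component {comp.species!r} has no "
                        f"site {site_name!r}",
                        comp.loc,
                    )
    return issues


def _match_products_to_reactants(rxn: ReactionAST) -> Dict[int, Optional[int]]:
    """Match product occurrences to reactant occurrences of the same
    species, in order of appearance (first product of S pairs with the
    first reactant of S, and so on)."""
    used: Dict[int, bool] = {}
    mapping: Dict[int, Optional[int]] = {}
    for pi, pref in enumerate(rxn.products):
        match = None
        for ri, rref in enumerate(rxn.reactants):
            if rref.species == pref.species and not used.get(ri):
                match = ri
                used[ri] = True
                break
        mapping[pi] = match
    return mapping


def _validate_reaction(model, idx, rxn, issues, err, warn, check_expr) -> None:
    genv = model.globals
    label = f"reaction {idx + 1}"

    def species_of(ref: SpeciesRefAST) -> Optional[MultistateSpecies]:
        sp = model.species.get(ref.species)
        if sp is None:
            err(
                "undef-species",
                f"{label}: species {ref.species!r} is not defined",
                ref.loc,
            )
        return sp

    # reactant patterns ----------------------------------------------------
    reactant_admitted: List[Dict[str, List[Label]]] = []
    for ref in rxn.reactants:
        sp = species_of(ref)
        admitted: Dict[str, List[Label]] = {}
        if sp is None:
            reactant_admitted.append(admitted)
            continue
        for site_name, pat in ref.site_patterns:
            sd = sp.site(site_name)
            if sd is None:
                err(
                    "undef-site",
                    f"{label}: species {ref.species!r} has no site {site_name!r}",
                    ref.loc,
                )
                continue
            if isinstance(pat, (OpCall, Transfer)):
                err(
                    "operator-in-reactant",
                    f"{label}: {type(pat).__name__} pattern is only legal in "
                    f"products or modifiers",
                    getattr(pat, "loc", None) or ref.loc,
                )
                continue
            try:
                states = resolve_state_list(sd, genv)
                labels = admitted_labels(pat, states, genv)
                admitted[site_name] = labels
                if not labels:
                    warn(
                        "empty-range",
                        f"{label}: pattern on {ref.species}.{site_name} admits no states",
                        getattr(pat, "loc", None) or ref.loc,
                    )
            except StaticEvalError as exc:
                err("non-static-range", f"{label}: {exc}", ref.loc)
            except StateOrderError as exc:
                err("bad-fixed-state", f"{label}: {exc}", ref.loc)
        # unmentioned sites admit their full state list
        for sd in sp.sites:
            if sd.name not in admitted and ref.pattern_for(sd.name) is None:
                try:
                    admitted[sd.name] = list(resolve_state_list(sd, genv).labels)
                except StaticEvalError:
                    pass
        reactant_admitted.append(admitted)

    mapping = _match_products_to_reactants(rxn)

    def source_values(src_species: str, src_site: str) -> Optional[List[Label]]:
        """All values src_species.src_site may take across the reactants."""
        for ri, rref in enumerate(rxn.reactants):
            if rref.species == src_species:
                return reactant_admitted[ri].get(src_site)
        return None

    # products and modifiers ----------------------------------------------
    for pi, ref in enumerate(rxn.products):
        sp = species_of(ref)
        if sp is None:
            continue
        matched = mapping.get(pi)
        for site_name, pat in ref.site_patterns:
            sd = sp.site(site_name)
            if sd is None:
                err(
                    "undef-site",
                    f"{label}: species {ref.species!r} has no site {site_name!r}",
                    ref.loc,
                )
                continue
            if isinstance(pat, OpCall):
                _check_opcall(
                    model, label, rxn, matched, reactant_admitted, ref, sd, pat, err
                )
            elif isinstance(pat, Transfer):
                _check_transfer(model, label, ref, sd, pat, source_values, err)
        # every site of a closed multistate product must be determined
        for sd in sp.sites:
            if sd.states is None:
                continue
            pat = ref.pattern_for(sd.name)
            if pat is None and matched is None:
                err(
                    "underdetermined-product",
                    f"{label}: state of product {ref.species}.{sd.name} is "
                    "undetermined (no pattern and no matching reactant)",
                    ref.loc,
                )

    for ref in rxn.modifiers:
        sp = species_of(ref)
        if sp is None:
            continue
        for site_name, pat in ref.site_patterns:
            if sp.site(site_name) is None:
                err(
                    "undef-site",
                    f"{label}: species {ref.species!r} has no site {site_name!r}",
                    ref.loc,
                )
                continue
            if isinstance(pat, Transfer):
                _check_transfer(model, label, ref, sp.site(site_name), pat, source_values, err)

    # rate law -------------------------------------------------------------
    _validate_rate_law(model, label, rxn, err, check_expr)


def _check_opcall(model, label, rxn, matched, reactant_admitted, ref, sd, pat, err) -> None:
    genv = model.globals
    if matched is None:
        err(
            "operator-no-reactant",
            f"{label}: {pat.op}({pat.site}) on product {ref.species!r} has no "
            "matching reactant occurrence",
            pat.loc or ref.loc,
        )
        return
    source = reactant_admitted[matched].get(pat.site)
    if source is None:
        err(
            "undef-site",
            f"{label}: {pat.op}({pat.site}) refers to a site the matched reactant "
            "does not determine",
            pat.loc or ref.loc,
        )
        return
    try:
        states = resolve_state_list(sd, genv)
    except StaticEvalError:
        return
    for s in source:
        try:
            apply_op(pat.op, states, s)
        except StateOrderError as exc:
            err(
                "range-coherence",
                f"{label}: {exc} for species {ref.species}({sd.name})",
                pat.loc or ref.loc,
            )
            break


def _check_transfer(model, label, ref, target_sd, pat, source_values, err) -> None:
    genv = model.globals
    src_sp = model.species.get(pat.source_species)
    if src_sp is None or src_sp.site(pat.source_site) is None:
        err(
            "transfer-incompatible",
            f"{label}: transfer source {pat.source_species}.{pat.source_site} "
            "does not exist",
            pat.loc or ref.loc,
        )
        return
    values = source_values(pat.source_species, pat.source_site)
    if values is None:
        err(
            "transfer-incompatible",
            f"{label}: transfer source {pat.source_species}.{pat.source_site} is "
            "not determined by any reactant",
            pat.loc or ref.loc,
        )
        return
    try:
        src_states = resolve_state_list(src_sp.site(pat.source_site), genv)
        if target_sd.states is None:
            # open-site target (assigned modifier species): any value is legal
            if pat.op is not None:
                for s in values:
                    apply_op(pat.op, src_states, s)
            return
        target_states = resolve_state_list(target_sd, genv)
        for s in values:
            v = apply_op(pat.op, src_states, s)
            if v not in target_states.labels:
                err(
                    "transfer-incompatible",
                    f"{label}: transferred value {v!r} is not a legal state of "
                    f"{ref.species}.{target_sd.name}",
                    pat.loc or ref.loc,
                )
                break
    except StaticEvalError:
        pass
    except StateOrderError as exc:
        err("range-coherence", f"{label}: {exc}", pat.loc or ref.loc)


def _validate_rate_law(model, label, rxn, err, check_expr) -> None:
    law = rxn.rate_law
    if law is None:
        return
    if isinstance(law, MassActionLaw):
        check_expr(law.rate, loc=law.loc, context=f"rate law of {label}")
        return
    if isinstance(law, RawKineticLaw):
        check_expr(law.expr, loc=law.loc, context=f"rate law of {label}")
        return
    if isinstance(law, UserDefinedLaw):
        fn = model.functions.get(law.func)
        if fn is None:
            err(
                "undef-identifier",
                f"{label}: rate-law function {law.func!r} is not defined",
                law.loc,
            )
            return
        if len(law.args) != len(fn.params):
            err(
                "func-arity",
                f"{label}: function {law.func!r} takes {len(fn.params)} arguments, "
                f"got {len(law.args)}",
                law.loc,
            )
            return
        for arg, (pname, role) in zip(law.args, fn.params):
            if role == "SITE":
                if not isinstance(arg, SiteAccess):
                    err(
                        "func-role",
                        f"{label}: argument for SITE parameter {pname!r} must be a "
                        "species.site accessor",
                        law.loc,
                    )
                else:
                    check_expr(arg, loc=law.loc, context=f"rate law of {label}")
            elif role == "SUB":
                if not isinstance(arg, Name) or arg.ident not in model.species:
                    err(
                        "func-role",
                        f"{label}: argument for SUB parameter {pname!r} must be a "
                        "species",
                        law.loc,
                    )
            elif role == "GLQ":
                if not isinstance(arg, (Name, Num)):
                    err(
                        "func-role",
                        f"{label}: argument for GLQ parameter {pname!r} must be a "
                        "global quantity or number",
                        law.loc,
                    )
                elif isinstance(arg, Name) and arg.ident not in model.globals:
                    err(
                        "undef-identifier",
                        f"{label}: {arg.ident!r} is not a defined global quantity",
                        law.loc,
                    )


# ---------------------------------------------------------------------------
# rename
# ---------------------------------------------------------------------------

def rename_entity(model: Model, old_name: str, new_name: str) -> Model:
    """Return a copy of *model* with *old_name* renamed to *new_name*.

    ``old_name`` may be a plain entity name (species, global quantity,
    function, complex) or a dotted ``Species.site`` to rename a site; the
    change propagates to every reference (reactions, expressions, SUM
    aggregates, complexes, rate laws). Auto-named complexes containing a
    renamed component regenerate their name. Raises :class:`ValueError`
    on a name collision or unknown entity; the input model is unchanged.
    """
    if "." in old_name:
        species, _, site = old_name.partition(".")
        return _rename_site(model, species, site, new_name)
    if old_name == new_name:
        return model.copy()
    if not is_legal_identifier(new_name):
        raise ValueError(f"{new_name!r} is not a legal identifier")
    taken = (
        set(model.species) | set(model.globals) | set(model.functions) | set(model.complexes)
    )
    if new_name in taken:
        raise ValueError(f"name {new_name!r} is already in use")
    if old_name not in taken:
        raise ValueError(f"no entity named {old_name!r}")

    m = model.copy()

    def rewrite_expr(expr: Expr) -> None:
        for kind, node in iter_names(expr):
            if kind == "name" and node.ident == old_name:
                node.ident = new_name
            elif kind == "site" and node.species == old_name:
                node.species = new_name
            elif kind == "call" and node.func == old_name:
                node.func = new_name
            elif kind == "sum" and node.species == old_name:
                node.species = new_name

    def rewrite_ref(ref: SpeciesRefAST) -> None:
        if ref.species == old_name:
            ref.species = new_name
        for _, pat in ref.site_patterns:
            if isinstance(pat, Transfer) and pat.source_species == old_name:
                pat.source_species = new_name
            elif isinstance(pat, FixedState):
                rewrite_expr(pat.value)
            elif isinstance(pat, RangePattern):
                if pat.lo is not None:
                    rewrite_expr(pat.lo)
                if pat.hi is not None:
                    rewrite_expr(pat.hi)

    for rxn in m.reactions:
        for ref in rxn.reactants + rxn.products + rxn.modifiers:
            rewrite_ref(ref)
        if isinstance(rxn.rate_law, MassActionLaw):
            rewrite_expr(rxn.rate_law.rate)
        elif isinstance(rxn.rate_law, UserDefinedLaw):
            if rxn.rate_law.func == old_name:
                rxn.rate_law.func = new_name
            for a in rxn.rate_law.args:
                rewrite_expr(a)
        elif isinstance(rxn.rate_law, RawKineticLaw):
            rewrite_expr(rxn.rate_law.expr)
    for sp in m.species.values():
        for sd in sp.sites:
            if isinstance(sd.states, RangeSpec):
                rewrite_expr(sd.states.lo)
                rewrite_expr(sd.states.hi)
        if sp.default_initial is not None:
            rewrite_expr(sp.default_initial)
        if sp.assignment is not None:
            rewrite_expr(sp.assignment)
        for v in sp.per_state_initials.values():
            rewrite_expr(v)
    for g in m.globals.values():
        rewrite_expr(g.initial_expr)

    if old_name in m.species:
        m.species = {new_name if k == old_name else k: v for k, v in m.species.items()}
        m.species[new_name].name = new_name
    elif old_name in m.globals:
        m.globals = {new_name if k == old_name else k: v for k, v in m.globals.items()}
        m.globals[new_name].name = new_name
    elif old_name in m.functions:
        m.functions = {new_name if k == old_name else k: v for k, v in m.functions.items()}
        m.functions[new_name].name = new_name
    if old_name in m.complexes:  # a complex also owns its materialized species
        m.complexes = {new_name if k == old_name else k: v for k, v in m.complexes.items()}
        cx = m.complexes[new_name]
        cx.name = new_name
        cx.auto_named = False
        for sp in m.species.values():
            if sp.origin_complex == old_name:
                sp.origin_complex = new_name
        for rxn in m.reactions:
            if rxn.origin_complex == old_name:
                rxn.origin_complex = new_name

    # complexes referencing a renamed component regenerate auto-names
    for cx in list(m.complexes.values()):
        changed = False
        for comp in cx.components:
            if comp.species == old_name:
                comp.species = new_name
                changed = True
        if changed and cx.auto_named:
            fresh = "_".join(c.species for c in cx.components)
            if fresh != cx.name and fresh not in m.species and fresh not in m.complexes:
                m = rename_entity(m, cx.name, fresh)
                m.complexes[fresh].auto_named = True
    return m


def _rename_site(model: Model, species: str, old_site: str, new_site: str) -> Model:
    sp0 = model.species.get(species)
    if sp0 is None or sp0.site(old_site) is None:
        raise ValueError(f"no site {species}.{old_site}")
    if not is_legal_identifier(new_site):
        raise ValueError(f"{new_site!r} is not a legal identifier")
    if sp0.site(new_site) is not None:
        raise ValueError(f"species {species!r} already has a site {new_site!r}")
    m = model.copy()
    sp = m.species[species]
    for sd in sp.sites:
        if sd.name == old_site:
            sd.name = new_site

    def rewrite_expr(expr: Expr) -> None:
        for kind, node in iter_names(expr):
            if kind == "site" and node.species == species and node.site == old_site:
                node.site = new_site
            elif kind == "sum" and node.species == species:
                node.restrictions = [
                    (new_site if s == old_site else s, r) for s, r in node.restrictions
                ]

    def rewrite_ref(ref: SpeciesRefAST) -> None:
        for i, (site_name, pat) in enumerate(ref.site_patterns):
            if ref.species == species and site_name == old_site:
                ref.site_patterns[i] = (new_site, pat)
            if isinstance(pat, OpCall) and ref.species == species and pat.site == old_site:
                pat.site = new_site
            if (
                isinstance(pat, Transfer)
                and pat.source_species == species
                and pat.source_site == old_site
            ):
                pat.source_site = new_site

    for rxn in m.reactions:
        for ref in rxn.reactants + rxn.products + rxn.modifiers:
            rewrite_ref(ref)
        if isinstance(rxn.rate_law, MassActionLaw):
            rewrite_expr(rxn.rate_law.rate)
        elif isinstance(rxn.rate_law, UserDefinedLaw):
            for a in rxn.rate_law.args:
                rewrite_expr(a)
        elif isinstance(rxn.rate_law, RawKineticLaw):
            rewrite_expr(rxn.rate_law.expr)
    for s in m.species.values():
        if s.default_initial is not None:
            rewrite_expr(s.default_initial)
        if s.assignment is not None:
            rewrite_expr(s.assignment)
        for v in s.per_state_initials.values():
            rewrite_expr(v)
    for g in m.globals.values():
        rewrite_expr(g.initial_expr)
    for cx in m.complexes.values():
        for comp in cx.components:
            if comp.species == species:
                comp.tracked = [
                    (new_site if s == old_site else s, r) for s, r in comp.tracked
                ]
    return m


# ---------------------------------------------------------------------------
# delete
# ---------------------------------------------------------------------------

DeletePolicy = Union[str, Tuple[str, float]]  # 'cascade' | 'leave_dangling' | ('replace_with', v)


def delete_entity(
    model: Model,
    name: str,
    policy: Optional[DeletePolicy] = None,
    overrides: Optional[Dict[Tuple[str, object], DeletePolicy]] = None,
) -> Tuple[Model, List[ValidationIssue]]:
    """Delete *name*, resolving every reference per policy.

    ``policy`` applies to all references unless ``overrides`` supplies a
    per-reference policy, keyed by ``("reaction", index)``,
    ``("species", name)``, ``("global", name)`` or ``("complex", name)``.
    ``cascade`` removes the referencing element (reactions and complexes
    are removed; an expression-bearing entity is itself deleted, again
    with cascade). ``("replace_with", v)`` substitutes the number *v* into
    referencing expressions — it is rejected with an error issue where the
    reference is a reaction participant, since a number cannot take part
    in a reaction. ``leave_dangling`` keeps each reference and records an
    error issue for it. Nothing here is fatal.
    """
    m = model.copy()
    issues: List[ValidationIssue] = []
    default = policy if policy is not None else m.preferences.default_delete_policy
    overrides = overrides or {}
    _delete_one(m, name, default, overrides, issues)
    return m, issues


def _policy_parts(policy: DeletePolicy) -> Tuple[str, Optional[float]]:
    if isinstance(policy, tuple):
        return policy[0], policy[1]
    return policy, None


def _expr_references(expr: Expr, name: str) -> bool:
    for kind, node in iter_names(expr):
        if kind == "name" and node.ident == name:
            return True
        if kind in ("site", "sum") and node.species == name:
            return True
        if kind == "call" and node.func == name:
            return True
    return False


def _delete_one(m: Model, name: str, default, overrides, issues: List[ValidationIssue]) -> None:
    def policy_for(key):
        return overrides.get(key, default)

    def dangling(what: str, loc=None) -> None:
        issues.append(
            ValidationIssue(
                Severity.ERROR,
                "dangling-reference",
                f"{what} still references deleted entity {name!r}",
                loc,
            )
        )

    # reactions ------------------------------------------------------------
    kept_reactions: List[MultistateReaction] = []
    for idx, rxn in enumerate(m.reactions):
        refs = rxn.reactants + rxn.products + rxn.modifiers
        participant = any(ref.species == name for ref in refs)
        transfer_src = any(
            isinstance(pat, Transfer) and pat.source_species == name
            for ref in refs
            for _, pat in ref.site_patterns
        )
        law_ref = False
        if isinstance(rxn.rate_law, MassActionLaw):
            law_ref = _expr_references(rxn.rate_law.rate, name)
        elif isinstance(rxn.rate_law, UserDefinedLaw):
            law_ref = rxn.rate_law.func == name or any(
                _expr_references(a, name) for a in rxn.rate_law.args
            )
        elif isinstance(rxn.rate_law, RawKineticLaw):
            law_ref = _expr_references(rxn.rate_law.expr, name)
        if not (participant or transfer_src or law_ref):
            kept_reactions.append(rxn)
            continue
        kind, value = _policy_parts(policy_for(("reaction", idx)))
        if kind == "cascade":
            continue  # drop the reaction
        if kind == "replace_with":
            if participant or transfer_src:
                issues.append(
                    ValidationIssue(
                        Severity.ERROR,
                        "replace-in-reaction",
                        f"cannot replace reaction participant {name!r} with a "
                        "number; reference left dangling",
                        rxn.loc,
                    )
                )
                kept_reactions.append(rxn)
                continue
            if isinstance(rxn.rate_law, MassActionLaw):
                rxn.rate_law.rate = substitute_name(rxn.rate_law.rate, name, Num(value))
            elif isinstance(rxn.rate_law, UserDefinedLaw):
                rxn.rate_law.args = [
                    substitute_name(a, name, Num(value)) for a in rxn.rate_law.args
                ]
            elif isinstance(rxn.rate_law, RawKineticLaw):
                rxn.rate_law.expr = substitute_name(rxn.rate_law.expr, name, Num(value))
            kept_reactions.append(rxn)
            continue
        # leave_dangling
        dangling(f"reaction {idx + 1}", rxn.loc)
        kept_reactions.append(rxn)
    m.reactions = kept_reactions

    # expression-bearing entities -------------------------------------------
    for sp in list(m.species.values()):
        if sp.name == name:
            continue
        exprs = [e for e in (sp.default_initial, sp.assignment) if e is not None]
        exprs += list(sp.per_state_initials.values())
        if not any(_expr_references(e, name) for e in exprs):
            continue
        kind, value = _policy_parts(policy_for(("species", sp.name)))
        if kind == "cascade":
            _delete_one(m, sp.name, default, overrides, issues)
            m.species.pop(sp.name, None)
        elif kind == "replace_with":
            if sp.default_initial is not None:
                sp.default_initial = substitute_name(sp.default_initial, name, Num(value))
            if sp.assignment is not None:
                sp.assignment = substitute_name(sp.assignment, name, Num(value))
            for key in list(sp.per_state_initials):
                sp.per_state_initials[key] = substitute_name(
                    sp.per_state_initials[key], name, Num(value)
                )
        else:
            dangling(f"species {sp.name!r}")

    for g in list(m.globals.values()):
        if g.name == name or not _expr_references(g.initial_expr, name):
            continue
        kind, value = _policy_parts(policy_for(("global", g.name)))
        if kind == "cascade":
            _delete_one(m, g.name, default, overrides, issues)
            m.globals.pop(g.name, None)
        elif kind == "replace_with":
            g.initial_expr = substitute_name(g.initial_expr, name, Num(value))
        else:
            dangling(f"global quantity {g.name!r}")

    # complexes containing the deleted component -----------------------------
    for cx in list(m.complexes.values()):
        if any(comp.species == name for comp in cx.components):
            kind, _ = _policy_parts(policy_for(("complex", cx.name)))
            if kind == "cascade":
                _delete_one(m, cx.name, default, overrides, issues)
                m.complexes.pop(cx.name, None)
                m.species.pop(cx.name, None)
                m.reactions = [r for r in m.reactions if r.origin_complex != cx.name]
            else:
                dangling(f"complex {cx.name!r}")

    # finally remove the entity itself ---------------------------------------
    if name in m.species:
        del m.species[name]
    if name in m.globals:
        del m.globals[name]
    if name in m.functions:
        del m.functions[name]
    if name in m.complexes:
        cx = m.complexes.pop(name)
        m.species.pop(name, None)
        m.reactions = [r for r in m.reactions if r.origin_complex != name]


# ---------------------------------------------------------------------------
# complexes
# ---------------------------------------------------------------------------

def build_complex(
    model: Model,
    components,
    name: Optional[str] = None,
    generate_reactions: bool = False,
) -> Tuple[ComplexSpecies, List[MultistateReaction]]:
    """Add a complex species built from *components* to *model*.

    Components are :class:`~multistate._ast.ComplexComponentAST` (or
    ``(species, [(site, (lo, hi) | None), ...])`` tuples). Tracked sites
    are copied onto the complex, restricted to the given subrange;
    unrestricted tracked sites copy the component's full state list. When
    no name is given, the complex is auto-named by joining its component
    names (and the name follows component renames). With
    ``generate_reactions`` the complexation reaction (components ->
    complex, state transferred from each tracked site) and its reverse
    are added, with mass-action rate constants ``kon_<name>`` /
    ``koff_<name>`` created as globals when missing.

    The complex does not model individual bonds: it is a flattened
    species whose sites are copies of the tracked component sites.
    Components may not themselves be complexes (no nesting).
    """
    comps: List[ComplexComponentAST] = []
    for c in components:
        if isinstance(c, ComplexComponentAST):
            comps.append(c)
        else:
            species, tracked = c
            comps.append(
                ComplexComponentAST(
                    species,
                    [
                        (site, None if r is None else RangeExpr(Num(r[0]), Num(r[1])))
                        for site, r in tracked
                    ],
                )
            )
    for c in comps:
        sp = model.species.get(c.species)
        if sp is None:
            raise ValueError(f"complex component {c.species!r} is not defined")
        if c.species in model.complexes:
            raise ValueError(f"complex component {c.species!r} is itself a complex (nesting is not supported)")
        for site_name, restriction in c.tracked:
            sd = sp.site(site_name)
            if sd is None:
                raise ValueError(f"component {c.species!r} has no site {site_name!r}")
            if restriction is not None:
                states = resolve_state_list(sd, model.globals)
                lo = evaluate_static(restriction.lo, model.globals)
                hi = evaluate_static(restriction.hi, model.globals)
                numeric = [s for s in states.labels if isinstance(s, int)]
                if not numeric or lo < min(numeric) or hi > max(numeric):
                    raise ValueError(
                        f"restriction {site_name}{{{lo}:{hi}}} is outside the state "
                        f"list of {c.species}.{site_name}"
                    )

    auto_named = name is None
    cx_name = name or "_".join(c.species for c in comps)
    if cx_name in model.species or cx_name in model.complexes:
        raise ValueError(f"name {cx_name!r} is already in use")

    # complex sites: tracked component sites, prefixed on collision
    counts: Dict[str, int] = {}
    for c in comps:
        for site_name, _ in c.tracked:
            counts[site_name] = counts.get(site_name, 0) + 1
    sites: List[SiteDefAST] = []
    site_map: Dict[str, Tuple[str, str]] = {}
    for c in comps:
        sp = model.species[c.species]
        for site_name, restriction in c.tracked:
            sd = sp.site(site_name)
            cx_site = site_name if counts[site_name] == 1 else f"{c.species}_{site_name}"
            if restriction is not None:
                lo = evaluate_static(restriction.lo, model.globals)
                hi = evaluate_static(restriction.hi, model.globals)
                states: Union[RangeSpec, EnumSpec] = RangeSpec(Num(lo), Num(hi))
            else:
                states = copy.deepcopy(sd.states)
            sites.append(SiteDefAST(cx_site, states, sd.circular))
            site_map[cx_site] = (c.species, site_name)

    cx_species = MultistateSpecies(
        cx_name, sites, default_initial=Num(0), origin_complex=cx_name
    )
    model.species[cx_name] = cx_species
    cx = ComplexSpecies(cx_name, comps, generate_reactions, auto_named, site_map)
    model.complexes[cx_name] = cx

    reactions: List[MultistateReaction] = []
    if generate_reactions:
        for rate_name in (f"kon_{cx_name}", f"koff_{cx_name}"):
            if rate_name not in model.globals:
                model.globals[rate_name] = GlobalQuantity(rate_name, "fixed", Num(1))
        # complexation: components (restricted ranges) -> complex (transfer)
        reactant_refs = []
        for c in comps:
            patterns: List[Tuple[str, Pattern]] = []
            for site_name, restriction in c.tracked:
                if restriction is not None:
                    patterns.append(
                        (site_name, RangePattern(restriction.lo, restriction.hi))
                    )
                else:
                    patterns.append((site_name, RangePattern(None, None)))
            reactant_refs.append(SpeciesRefAST(c.species, patterns))
        product_patterns: List[Tuple[str, Pattern]] = [
            (cx_site, Transfer(src_sp, src_site))
            for cx_site, (src_sp, src_site) in site_map.items()
        ]
        complexation = MultistateReaction(
            reactant_refs,
            [SpeciesRefAST(cx_name, product_patterns)],
            [],
            MassActionLaw(Name(f"kon_{cx_name}")),
            origin_complex=cx_name,
        )
        # decomplexation: complex (full tracked ranges) -> components (transfer)
        decomp_products = []
        for c in comps:
            patterns = []
            for site_name, _ in c.tracked:
                cx_site = site_name if counts[site_name] == 1 else f"{c.species}_{site_name}"
                patterns.append((site_name, Transfer(cx_name, cx_site)))
            decomp_products.append(SpeciesRefAST(c.species, patterns))
        decomplexation = MultistateReaction(
            [SpeciesRefAST(cx_name, [(s.name, RangePattern(None, None)) for s in sites])],
            decomp_products,
            [],
            MassActionLaw(Name(f"koff_{cx_name}")),
            origin_complex=cx_name,
        )
        reactions = [complexation, decomplexation]
        model.reactions.extend(reactions)
    return cx, reactions


# ---------------------------------------------------------------------------
# convenience: text -> model
# ---------------------------------------------------------------------------

def load_model(
    document: str,
    autocompletion_policy: Optional[str] = None,
    preferences: Optional[Preferences] = None,
) -> Tuple[Model, List[ValidationIssue]]:
    """Parse a ``.msl`` document and build the semantic model.

    Returned issues combine parse diagnostics with build diagnostics.
    """
    from .parser import parse_model

    ast, parse_issues = parse_model(document)
    model, build_issues = build_model(ast, autocompletion_policy, preferences)
    return model, parse_issues + build_issues
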