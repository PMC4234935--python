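"""Expansion of a multistate model into the flat single-state network.

A multistate reaction is a template: every combination of states admitted
by its reactant patterns yields one flat reaction, with product states
resolved through fixed values, carry-over from the matched reactant,
succ/pred, or transfer of state, and with the kinetic law instantiated
per combination (mass action over the flat instances, or a user-defined
function with GLQ/SITE/SUB parameter roles bound).

Flat naming scheme (stable, documented): ``base_siteLabel`` joined with
underscores over the sites in declaration order — ``Cdh1(p=3)`` becomes
``Cdh1_p3``, a two-site instance ``X(a=0, b=free)`` becomes
``X_a0_bfree``; a zero-site species keeps its name. Name collisions are
resolved deterministically by appending ``_2``, ``_3``, ... in encounter
order.

Expansion is deterministic: species instances enumerate sites in
declaration order with the last site varying fastest, and reactions are
expanded in model order, so two runs on the same model produce identical
output.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

from ._ast import (
    BinOp,
    Call,
    Expr,
    FixedState,
    MassActionLaw,
    Name,
    Num,
    OpCall,
    RangePattern,
    RawKineticLaw,
    SiteAccess,
    SpeciesRefAST,
    SumNode,
    Transfer,
    UnaryOp,
    UserDefinedLaw,
)
from .issues import Severity, ValidationIssue, errors
from .model import (
    Model,
    MultistateReaction,
    MultistateSpecies,
    _match_products_to_reactants,
    admitted_labels,
    validate,
)
from .states import (
    Label,
    StateList,
    StaticEvalError,
    apply_op,
    eval_number,
    evaluate_static,
    resolve_state_list,
)

__all__ = [
    "FlatSpecies",
    "FlatReaction",
    "FlatModel",
    "ExpansionError",
    "flat_name",
    "enumerate_instances",
    "expand_reaction",
    "expand_sum",
    "instantiate_rate_law",
    "expand_model",
]


class ExpansionError(ValueError):
    """Raised when a model cannot be expanded (outstanding errors, or an
    inconsistency the validator should have caught)."""

    def __init__(self, message: str, issues: Optional[List[ValidationIssue]] = None):
        super().__init__(message)
        self.issues = issues or []


@dataclass(frozen=True)
class FlatSpecies:
    """One fully grounded state of a multistate species."""

    name: str
    base: str
    assignment: Tuple[Tuple[str, Label], ...]  # (site, label) in site order
    initial: float = 0.0


@dataclass
class FlatReaction:
    name: str
    reactants: List[str]
    products: List[str]
    modifiers: List[str]
    kinetic: Optional[Expr] = None

    def reaction_string(self) -> str:
        text = " + ".join(self.reactants) + " -> " + " + ".join(self.products)
        text = text.strip()
        if self.modifiers:
            text += " ; " + ", ".join(self.modifiers)
        return text


@dataclass
class FlatModel:
    """The expanded single-state network."""

    species: List[FlatSpecies] = field(default_factory=list)
    reactions: List[FlatReaction] = field(default_factory=list)
    parameters: Dict[str, float] = field(default_factory=dict)
    # (target name, grounded expression); SUM-defined globals and
    # per-instance modifiers land here
    assignment_rules: List[Tuple[str, Expr]] = field(default_factory=list)
    issues: List[ValidationIssue] = field(default_factory=list)

    def species_names(self) -> List[str]:
        return [s.name for s in self.species]


def flat_name(base: str, assignment: Tuple[Tuple[str, Label], ...]) -> str:
    if not assignment:
        return base
    return base + "".join(f"_{site}{label}" for site, label in assignment)


# ---------------------------------------------------------------------------
# species instance enumeration
# ---------------------------------------------------------------------------

def enumerate_instances(
    species: MultistateSpecies, globals_env=None
) -> List[FlatSpecies]:
    """All fully grounded states of *species*, in deterministic order.

    The cartesian product runs over the sites in declaration order with
    the last site varying fastest. Initial amounts come from the
    per-state overrides, falling back to the species default.
    """
    genv = globals_env or {}
    site_lists: List[Tuple[str, StateList]] = [
        (sd.name, resolve_state_list(sd, genv)) for sd in species.sites
    ]
    default = 0.0
    if species.default_initial is not None:
        try:
            default = eval_number(species.default_initial, genv)
        except StaticEvalError:
            default = 0.0
    combos: List[Tuple[Tuple[str, Label], ...]] = [()]
    for site_name, states in site_lists:
        combos = [c + ((site_name, s),) for c in combos for s in states.labels]
    out = []
    for combo in combos:
        key = tuple(label for _, label in combo)
        initial = default
        if key in species.per_state_initials:
            try:
                initial = eval_number(species.per_state_initials[key], genv)
            except StaticEvalError:
                initial = default
        out.append(FlatSpecies(flat_name(species.name, combo), species.name, combo, initial))
    return out


# ---------------------------------------------------------------------------
# expression grounding helpers
# ---------------------------------------------------------------------------

def _substitute(expr: Expr, mapping: Dict[str, Expr]) -> Expr:
    """Replace bare names per *mapping* (used to instantiate function bodies)."""
    if isinstance(expr, Name):
        if expr.ident in mapping:
            import copy

            return copy.deepcopy(mapping[expr.ident])
        return expr
    if isinstance(expr, UnaryOp):
        return UnaryOp(expr.op, _substitute(expr.operand, mapping))
    if isinstance(expr, BinOp):
        return BinOp(expr.op, _substitute(expr.left, mapping), _substitute(expr.right, mapping))
    if isinstance(expr, Call):
        return Call(expr.func, [_substitute(a, mapping) for a in expr.args])
    return expr


def _product(terms: List[Expr]) -> Expr:
    node = terms[0]
    for t in terms[1:]:
        node = BinOp("*", node, t)
    return node


def _sum_terms(terms: List[Expr]) -> Expr:
    if not terms:
        return Num(0)
    node = terms[0]
    for t in terms[1:]:
        node = BinOp("+", node, t)
    return node


# ---------------------------------------------------------------------------
# SUM expansion
# ---------------------------------------------------------------------------

def expand_sum(
    sum_node: SumNode,
    model: Model,
    env: Optional[Dict[Tuple[str, str], int]] = None,
    clip: bool = False,
    names: Optional[Dict[Tuple[str, Tuple], str]] = None,
) -> Expr:
    """Ground a SUM aggregate to an explicit sum of flat-species terms.

    *env* supplies integer values for instance-dependent site accessors
    in the restriction bounds (the Eq-style moving window ``M.c+1 :
    M.c+14`` evaluates against the enclosing instance). With
    ``clip=False`` a restriction exceeding the species' state list is an
    error; with ``clip=True`` it is silently intersected with the list —
    the behavior instance-dependent windows need near a chain end.
    Each term is multiplied by the weight expression (with the site
    values substituted) when a weight is present.
    """
    sp = model.species.get(sum_node.species)
    if sp is None:
        raise ExpansionError(f"SUM over undefined species {sum_node.species!r}")
    genv = model.globals
    restr = dict(sum_node.restrictions)
    per_site: List[Tuple[str, List[Label]]] = []
    for sd in sp.sites:
        states = resolve_state_list(sd, genv)
        r = restr.get(sd.name)
        if r is None:
            per_site.append((sd.name, list(states.labels)))
            continue
        lo = evaluate_static(r.lo, genv, site_env=env)
        hi = evaluate_static(r.hi, genv, site_env=env)
        numeric = [s for s in states.labels if isinstance(s, int)]
        if not clip and numeric and (lo < min(numeric) or hi > max(numeric)):
            raise ExpansionError(
                f"SUM restriction {sd.name}{{{lo}:{hi}}} exceeds the state list of "
                f"{sp.name}.{sd.name}"
            )
        per_site.append((sd.name, [s for s in numeric if lo <= s <= hi]))
    combos: List[Tuple[Tuple[str, Label], ...]] = [()]
    for site_name, labels in per_site:
        combos = [c + ((site_name, s),) for c in combos for s in labels]
    terms: List[Expr] = []
    for combo in combos:
        name = (names or {}).get((sp.name, combo)) or flat_name(sp.name, combo)
        term: Expr = Name(name)
        if sum_node.weight is not None:
            w = sum_node.weight
            for site_name, label in combo:
                w = _substitute_site_access(w, sp.name, site_name, label)
            term = BinOp("*", w, term)
        terms.append(term)
    return _sum_terms(terms)


def _substitute_site_access(expr: Expr, species: str, site: str, label: Label) -> Expr:
    if isinstance(expr, SiteAccess) and expr.species == species and expr.site == site:
        if not isinstance(label, int):
            raise ExpansionError(
                f"state {label!r} of {species}.{site} is not numeric and cannot be "
                "used as a value"
            )
        return Num(label)
    if isinstance(expr, UnaryOp):
        return UnaryOp(expr.op, _substitute_site_access(expr.operand, species, site, label))
    if isinstance(expr, BinOp):
        return BinOp(
            expr.op,
            _substitute_site_access(expr.left, species, site, label),
            _substitute_site_access(expr.right, species, site, label),
        )
    if isinstance(expr, Call):
        return Call(
            expr.func,
            [_substitute_site_access(a, species, site, label) for a in expr.args],
        )
    return expr


# ---------------------------------------------------------------------------
# reaction expansion
# ---------------------------------------------------------------------------

@dataclass
class _Instance:
    """One admitted state combination of a reaction's reactants."""

    # per reactant occurrence: site -> label
    reactant_states: List[Dict[str, Label]]
    # first-occurrence lookup: species name -> occurrence index
    first_of: Dict[str, int]


def _reactant_combinations(
    rxn: MultistateReaction, model: Model
) -> Tuple[List[_Instance], List[ValidationIssue]]:
    genv = model.globals
    issues: List[ValidationIssue] = []
    axes: List[Tuple[int, str, List[Label]]] = []  # (occurrence, site, labels)
    first_of: Dict[str, int] = {}
    for ri, ref in enumerate(rxn.reactants):
        first_of.setdefault(ref.species, ri)
        sp = model.species[ref.species]
        for sd in sp.sites:
            states = resolve_state_list(sd, genv)
            pat = ref.pattern_for(sd.name)
            labels = admitted_labels(pat, states, genv)
            if not labels:
                issues.append(
                    ValidationIssue(
                        Severity.WARNING,
                        "empty-range",
                        f"pattern on {ref.species}.{sd.name} admits no states; "
                        "reaction expands to nothing",
                        ref.loc,
                    )
                )
            axes.append((ri, sd.name, labels))
    combos: List[List[Dict[str, Label]]] = [
        [dict() for _ in rxn.reactants]
    ]
    for ri, site_name, labels in axes:
        new: List[List[Dict[str, Label]]] = []
        for combo in combos:
            for s in labels:
                ext = [dict(d) for d in combo]
                ext[ri][site_name] = s
                new.append(ext)
        combos = new
    return [_Instance(c, first_of) for c in combos], issues


def _resolve_ref_states(
    ref: SpeciesRefAST,
    model: Model,
    inst: _Instance,
    rxn: MultistateReaction,
    matched: Optional[int],
) -> Tuple[Tuple[str, Label], ...]:
    """Ground one product/modifier reference for one instance."""
    genv = model.globals
    sp = model.species[ref.species]
    out: List[Tuple[str, Label]] = []
    for sd in sp.sites:
        pat = ref.pattern_for(sd.name)
        states = resolve_state_list(sd, genv)
        if pat is None:
            if sd.states is None:
                continue  # open site with no pattern: nothing to ground
            if matched is None:
                raise ExpansionError(
                    f"state of {ref.species}.{sd.name} is undetermined"
                )
            out.append((sd.name, inst.reactant_states[matched][sd.name]))
            continue
        if isinstance(pat, FixedState):
            from .model import resolve_fixed

            out.append((sd.name, resolve_fixed(pat.value, states, genv)))
        elif isinstance(pat, RangePattern):
            if pat.lo is None and pat.hi is None and matched is not None:
                out.append((sd.name, inst.reactant_states[matched][sd.name]))
            else:
                raise ExpansionError(
                    f"range pattern on product {ref.species}.{sd.name} is not a "
                    "grounded state"
                )
        elif isinstance(pat, OpCall):
            if matched is None:
                raise ExpansionError(
                    f"{pat.op}({pat.site}) on {ref.species!r} has no matching reactant"
                )
            src = inst.reactant_states[matched][pat.site]
            src_states = model.state_list(rxn.reactants[matched].species, pat.site)
            out.append((sd.name, apply_op(pat.op, src_states, src)))
        elif isinstance(pat, Transfer):
            src_ri = inst.first_of.get(pat.source_species)
            if src_ri is None:
                raise ExpansionError(
                    f"transfer source {pat.source_species!r} is not a reactant"
                )
            src = inst.reactant_states[src_ri][pat.source_site]
            src_states = model.state_list(pat.source_species, pat.source_site)
            value = apply_op(pat.op, src_states, src)
            if sd.states is not None and value not in states.labels:
                raise ExpansionError(
                    f"transferred value {value!r} is not a state of "
                    f"{ref.species}.{sd.name}"
                )
            out.append((sd.name, value))
        else:  # pragma: no cover
            raise ExpansionError(f"unknown pattern {type(pat).__name__}")
    return tuple(out)


@dataclass
class _ModifierInstance:
    species: str
    assignment: Tuple[Tuple[str, Label], ...]
    name: str


def expand_reaction(
    rxn: MultistateReaction,
    model: Model,
    names: Optional[Dict[Tuple[str, Tuple], str]] = None,
    modifier_registry: Optional[Dict[str, _ModifierInstance]] = None,
) -> List[FlatReaction]:
    """Expand one multistate reaction into its flat single-state batch.

    One flat reaction per combination of states admitted by the reactant
    patterns (unmentioned sites of a multistate reactant iterate over
    their full state list). *names* optionally maps (base, assignment) to
    the final flat name (collision-resolved by :func:`expand_model`);
    *modifier_registry* collects per-instance modifier species so their
    assignment rules can be emitted once.
    """
    names = names or {}
    combos, _ = _reactant_combinations(rxn, model)
    mapping = _match_products_to_reactants(rxn)
    flat: List[FlatReaction] = []

    def resolved_name(base: str, assignment: Tuple[Tuple[str, Label], ...]) -> str:
        return names.get((base, assignment)) or flat_name(base, assignment)

    for inst in combos:
        reactant_names = []
        for ri, ref in enumerate(rxn.reactants):
            sp = model.species[ref.species]
            assignment = tuple(
                (sd.name, inst.reactant_states[ri][sd.name]) for sd in sp.sites
            )
            reactant_names.append(resolved_name(ref.species, assignment))
        product_names = []
        for pi, ref in enumerate(rxn.products):
            assignment = _resolve_ref_states(ref, model, inst, rxn, mapping.get(pi))
            product_names.append(resolved_name(ref.species, assignment))
        modifier_names = []
        for ref in rxn.modifiers:
            assignment = _resolve_ref_states(ref, model, inst, rxn, None)
            mname = resolved_name(ref.species, assignment)
            modifier_names.append(mname)
            if modifier_registry is not None and mname not in modifier_registry:
                modifier_registry[mname] = _ModifierInstance(
                    ref.species, assignment, mname
                )
        kinetic = None
        if rxn.rate_law is not None:
            kinetic = instantiate_rate_law(
                _RateContext(rxn, inst, reactant_names, model), rxn.rate_law, model
            )
        flat.append(
            FlatReaction(
                name="",  # assigned sequentially by expand_model
                reactants=reactant_names,
                products=product_names,
                modifiers=modifier_names,
                kinetic=kinetic,
            )
        )
    return flat


# ---------------------------------------------------------------------------
# rate-law instantiation
# ---------------------------------------------------------------------------

@dataclass
class _RateContext:
    rxn: MultistateReaction
    inst: _Instance
    reactant_names: List[str]
    model: Model

    def state_of(self, species: str, site: str) -> Label:
        ri = self.inst.first_of.get(species)
        if ri is None or site not in self.inst.reactant_states[ri]:
            raise ExpansionError(
                f"{species}.{site} is not determined by the reactants of this reaction"
            )
        return self.inst.reactant_states[ri][site]

    def instance_name(self, species: str) -> str:
        ri = self.inst.first_of.get(species)
        if ri is None:
            raise ExpansionError(f"{species!r} is not a reactant of this reaction")
        return self.reactant_names[ri]


def instantiate_rate_law(context: _RateContext, rate_law, model: Model) -> Expr:
    """Ground a rate law for one flat reaction instance.

    Mass action: rate-constant expression times the product of the flat
    reactant instance names. User-defined: the function body with GLQ
    arguments bound to globals/numbers, SUB arguments bound to the flat
    instance name of the referenced species, and SITE arguments bound to
    the numeric state value of the referenced site in this instance (a
    non-integer state label cannot be bound and is an error).
    """
    if isinstance(rate_law, RawKineticLaw):
        return rate_law.expr  # already a grounded kinetic expression
    if isinstance(rate_law, MassActionLaw):
        terms: List[Expr] = [rate_law.rate]
        terms.extend(Name(n) for n in context.reactant_names)
        return _product(terms)
    if isinstance(rate_law, UserDefinedLaw):
        fn = model.functions.get(rate_law.func)
        if fn is None:
            raise ExpansionError(f"rate-law function {rate_law.func!r} is not defined")
        if len(rate_law.args) != len(fn.params):
            raise ExpansionError(
                f"function {rate_law.func!r} takes {len(fn.params)} arguments, "
                f"got {len(rate_law.args)}"
            )
        mapping: Dict[str, Expr] = {}
        for arg, (pname, role) in zip(rate_law.args, fn.params):
            if role == "SITE":
                if not isinstance(arg, SiteAccess):
                    raise ExpansionError(
                        f"SITE parameter {pname!r} needs a species.site argument"
                    )
                value = context.state_of(arg.species, arg.site)
                if not isinstance(value, int):
                    raise ExpansionError(
                        f"state {value!r} of {arg.species}.{arg.site} is not an "
                        "integer and cannot be passed to a kinetic function"
                    )
                mapping[pname] = Num(value)
            elif role == "SUB":
                if not isinstance(arg, Name):
                    raise ExpansionError(
                        f"SUB parameter {pname!r} needs a species argument"
                    )
                mapping[pname] = Name(context.instance_name(arg.ident))
            else:  # GLQ
                mapping[pname] = arg
        return _substitute(fn.body, mapping)
    raise ExpansionError(f"unknown rate law {type(rate_law).__name__}")


# ---------------------------------------------------------------------------
# whole-model expansion
# ---------------------------------------------------------------------------

def expand_model(model: Model) -> FlatModel:
    """Expand the whole model; refuses if validation finds errors.

    Produces the flat species list (with collision-free deterministic
    names), the flat reactions (named ``r1``, ``r2``, ... in expansion
    order), parameters from fixed globals, and assignment rules for
    SUM-defined globals, assigned species, and per-instance reaction
    modifiers.
    """
    issues = validate(model)
    errs = errors(issues)
    if errs:
        listing = "; ".join(str(e) for e in errs)
        raise ExpansionError(
            f"cannot expand a model with {len(errs)} outstanding error(s): {listing}",
            errs,
        )
    flat = FlatModel(issues=[i for i in issues if i.severity is not Severity.ERROR])
    genv = model.globals

    # species instances, with deterministic collision handling -------------
    used: Dict[str, int] = {}
    names: Dict[Tuple[str, Tuple], str] = {}

    def claim(name: str) -> str:
        if name not in used:
            used[name] = 1
            return name
        used[name] += 1
        fresh = f"{name}_{used[name]}"
        while fresh in used:
            used[name] += 1
            fresh = f"{name}_{used[name]}"
        used[fresh] = 1
        flat.issues.append(
            ValidationIssue(
                Severity.WARNING,
                "name-collision",
                f"flat name {name!r} already taken; using {fresh!r}",
            )
        )
        return fresh

    open_species = {
        sp.name
        for sp in model.species.values()
        if any(sd.states is None for sd in sp.sites)
    }
    for sp in model.species.values():
        if sp.name in open_species:
            continue  # instances materialize from modifier references
        for fs in enumerate_instances(sp, genv):
            final = claim(fs.name)
            names[(fs.base, fs.assignment)] = final
            flat.species.append(
                FlatSpecies(final, fs.base, fs.assignment, fs.initial)
            )

    # reactions -------------------------------------------------------------
    modifier_registry: Dict[str, _ModifierInstance] = {}
    for rxn in model.reactions:
        _, warns = _reactant_combinations(rxn, model)
        flat.issues.extend(warns)
        for fr in expand_reaction(rxn, model, names, modifier_registry):
            fr.name = f"r{len(flat.reactions) + 1}"
            flat.reactions.append(fr)

    # per-instance modifier species and their assignment rules --------------
    for mname, minst in modifier_registry.items():
        if any(fs.name == mname for fs in flat.species):
            continue  # modifier resolved to an ordinary enumerated instance
        final = claim(mname)
        if final != mname:  # collision with an enumerated name: repoint uses
            for fr in flat.reactions:
                fr.modifiers = [final if m == mname else m for m in fr.modifiers]
        names[(minst.species, minst.assignment)] = final
        flat.species.append(FlatSpecies(final, minst.species, minst.assignment, 0.0))
        sp = model.species[minst.species]
        if sp.assignment is not None:
            env = {(sp.name, site): label for site, label in minst.assignment}
            rule = _ground_expr(sp.assignment, model, env, names, clip=True)
            flat.assignment_rules.append((final, rule))

    # globals ----------------------------------------------------------------
    for g in model.globals.values():
        if g.role == "fixed":
            try:
                flat.parameters[g.name] = eval_number(g.initial_expr, genv)
            except StaticEvalError:
                flat.assignment_rules.append(
                    (g.name, _ground_expr(g.initial_expr, model, None, names))
                )
        else:
            flat.assignment_rules.append(
                (g.name, _ground_expr(g.initial_expr, model, None, names))
            )

    # assigned plain species (no sites) --------------------------------------
    for sp in model.species.values():
        if sp.assignment is not None and not sp.sites:
            flat.assignment_rules.append(
                (names[(sp.name, ())], _ground_expr(sp.assignment, model, None, names))
            )
    return flat


def _ground_expr(
    expr: Expr,
    model: Model,
    env: Optional[Dict[Tuple[str, str], int]],
    names: Dict[Tuple[str, Tuple], str],
    clip: bool = False,
) -> Expr:
    """Ground SUM nodes and instance site accessors inside an expression."""
    if isinstance(expr, SumNode):
        return expand_sum(expr, model, env, clip=clip, names=names)
    if isinstance(expr, SiteAccess):
        if env is not None and (expr.species, expr.site) in env:
            return Num(env[(expr.species, expr.site)])
        return expr
    if isinstance(expr, UnaryOp):
        return UnaryOp(expr.op, _ground_expr(expr.operand, model, env, names, clip))
    if isinstance(expr, BinOp):
        return BinOp(
            expr.op,
            _ground_expr(expr.left, model, env, names, clip),
            _ground_expr(expr.right, model, env, names, clip),
        )
    if isinstance(expr, Call):
        return Call(
            expr.func, [_ground_expr(a, model, env, names, clip) for a in expr.args]
        )
    if isinstance(expr, Name) and expr.ident in model.species:
        sp = model.species[expr.ident]
        if not sp.sites:
            return Name(names.get((expr.ident, ()), expr.ident))
        # a bare multistate species name in an expression means its total
        return expand_sum(SumNode(expr.ident, []), model, env, clip=clip, names=names)
    return expr
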