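"""Canonical text generation for AST nodes.

``parse_model(unparse(ast))`` is structurally equal to ``ast``: state-list
order, site order and block order are preserved verbatim (the language
attaches meaning to declaration order, so nothing is ever sorted).
"""
from __future__ import annotations

from typing import Optional

from ._ast import (
    BinOp,
    Call,
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

_PRECEDENCE = {"+": 1, "-": 1, "*": 2, "/": 2, "^": 3}


def _num(value) -> str:
    if float(value) == int(value):
        return str(int(value))
    return repr(float(value))


def unparse_expr(e: Expr, parent_prec: int = 0) -> str:
    if isinstance(e, Num):
        return _num(e.value)
    if isinstance(e, Name):
        return e.ident
    if isinstance(e, SiteAccess):
        return f"{e.species}.{e.site}"
    if isinstance(e, UnaryOp):
        inner = unparse_expr(e.operand, 4)
        text = f"-{inner}"
        return f"({text})" if parent_prec > 1 else text
    if isinstance(e, BinOp):
        prec = _PRECEDENCE[e.op]
        left = unparse_expr(e.left, prec)
        # right child of a left-associative op needs a bump to re-parse equally
        right = unparse_expr(e.right, prec if e.op == "^" else prec + 1)
        text = f"{left}{e.op}{right}"
        return f"({text})" if prec < parent_prec else text
    if isinstance(e, Call):
        return f"{e.func}({','.join(unparse_expr(a) for a in e.args)})"
    if isinstance(e, SumNode):
        parts = [e.species]
        for site, r in e.restrictions:
            parts.append(f"{site}{{{_range_body(r.lo, r.hi)}}}")
        if e.weight is not None:
            parts.append(unparse_expr(e.weight))
        return f"SUM({';'.join(parts)})"
    raise TypeError(f"cannot unparse {type(e).__name__}")


def _range_body(lo, hi) -> str:
    if lo is hi or lo == hi:
        return unparse_expr(lo)
    return f"{unparse_expr(lo)}:{unparse_expr(hi)}"


def unparse_site(site: SiteDefAST) -> str:
    text = site.name
    if isinstance(site.states, RangeSpec):
        text += f"{{{unparse_expr(site.states.lo)}:{unparse_expr(site.states.hi)}}}"
    elif isinstance(site.states, EnumSpec):
        text += "{" + ",".join(str(l) for l in site.states.labels) + "}"
    if site.circular:
        text += "~circ"
    return text


def unparse_species(sp: SpeciesDefAST) -> str:
    text = sp.name
    if sp.sites:
        text += "(" + ", ".join(unparse_site(s) for s in sp.sites) + ")"
    if sp.assignment is not None:
        text += f" := {unparse_expr(sp.assignment)}"
    elif sp.default_initial is not None:
        text += f" = {unparse_expr(sp.default_initial)}"
    return text


def unparse_ref(ref: SpeciesRefAST) -> str:
    if not ref.site_patterns:
        return ref.species
    parts = []
    for site, pat in ref.site_patterns:
        if isinstance(pat, FixedState):
            parts.append(f"{site}{{{unparse_expr(pat.value)}}}")
        elif isinstance(pat, RangePattern):
            if pat.lo is None and pat.hi is None:
                parts.append(site)
            else:
                # never collapse lo==hi to a single value: p{3:3} and the
                # fixed pattern p{3} are distinct AST shapes
                parts.append(
                    f"{site}{{{unparse_expr(pat.lo)}:{unparse_expr(pat.hi)}}}"
                )
        elif isinstance(pat, OpCall):
            parts.append(f"{pat.op}({pat.site})")
        elif isinstance(pat, Transfer):
            src = f"{pat.source_species}.{pat.source_site}"
            rhs = f"{pat.op}({src})" if pat.op else src
            parts.append(f"{site}={rhs}")
        else:  # pragma: no cover
            raise TypeError(f"unknown pattern {type(pat).__name__}")
    return f"{ref.species}({', '.join(parts)})"


def unparse_reaction(rxn: ReactionAST) -> str:
    left = " + ".join(unparse_ref(r) for r in rxn.reactants)
    right = " + ".join(unparse_ref(r) for r in rxn.products)
    text = f"{left} -> {right}".strip()
    if rxn.modifiers:
        text += " ; " + ", ".join(unparse_ref(m) for m in rxn.modifiers)
    if isinstance(rxn.rate_law, MassActionLaw):
        text += f" : MA({unparse_expr(rxn.rate_law.rate)})"
    elif isinstance(rxn.rate_law, UserDefinedLaw):
        args = ",".join(unparse_expr(a) for a in rxn.rate_law.args)
        text += f" : UD({rxn.rate_law.func}({args}))"
    elif isinstance(rxn.rate_law, RawKineticLaw):
        text += f" : KIN({unparse_expr(rxn.rate_law.expr)})"
    return text


def unparse_global(g: GlobalQuantityAST) -> str:
    op = ":=" if g.role == "assigned" else "="
    return f"{g.name} {op} {unparse_expr(g.initial_expr)}"


def unparse_function(f: FunctionDefAST) -> str:
    params = ", ".join(f"{role} {name}" for name, role in f.params)
    return f"{f.name}({params}) = {unparse_expr(f.body)}"


def unparse_complex(c: ComplexDefAST) -> str:
    comps = []
    for comp in c.components:
        if comp.tracked:
            inner = []
            for site, r in comp.tracked:
                if r is None:
                    inner.append(site)
                else:
                    inner.append(f"{site}{{{_range_body(r.lo, r.hi)}}}")
            comps.append(f"{comp.species}({', '.join(inner)})")
        else:
            comps.append(comp.species)
    text = " + ".join(comps)
    if c.name is not None:
        text = f"{c.name} = {text}"
    if c.generate_reactions:
        text += " ~reactions"
    return text


def unparse_initial(init: StateInitialAST) -> str:
    inner = ", ".join(f"{site}{{{label}}}" for site, label in init.assignment)
    return f"{init.species}({inner}) = {unparse_expr(init.value)}"


def unparse(ast: ModelAST) -> str:
    """Serialize a full model AST to canonical ``.msl`` text."""
    out = []

    def block(header: str, entries, fmt) -> None:
        if entries:
            out.append(header + ":")
            out.extend(fmt(e) for e in entries)
            out.append("")

    block("species", ast.species, unparse_species)
    block("reactions", ast.reactions, unparse_reaction)
    block("globals", ast.globals, unparse_global)
    block("functions", ast.functions, unparse_function)
    block("complexes", ast.complexes, unparse_complex)
    block("initials", ast.initials, unparse_initial)
    return "\n".join(out)


def format_issue_location(loc: Optional[tuple]) -> str:  # pragma: no cover
    return f"{loc[0]}:{loc[1]}" if loc else "-"
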