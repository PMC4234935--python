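"""Recursive-descent parser for the multistate model language.

Single-construct entry points (:func:`parse_species`,
:func:`parse_reaction`, :func:`parse_expression`) raise
:class:`ParseError` with a line/column on malformed input.
:func:`parse_model` parses a sectioned document and *collects* per-entry
diagnostics instead of aborting — one bad line never loses the rest of
the file, so a model can be saved and reloaded with errors in it.

Document format (``.msl``): blank lines and ``#`` comments are ignored;
a line consisting of ``species:`` / ``reactions:`` / ``globals:`` /
``functions:`` / ``complexes:`` / ``initials:`` opens a section and every
following non-blank line is one entry of that section.

Grammar sketch (whitespace-insensitive)::

    species_def  := NAME [ '(' site_def (',' site_def)* ')' ] [ '=' expr | ':=' expr ]
    site_def     := NAME [ '{' states '}' ] [ '~' 'circ' ]
    states       := expr ':' expr | label (',' label)*
    reaction     := [refs] '->' refs [ ';' refs ] [ ':' rate_law ]
    ref          := NAME [ '(' pattern (',' pattern)* ')' ]
    pattern      := ('succ'|'pred') '(' NAME ')'
                  | NAME '=' ['succ('|'pred('] NAME '.' NAME [')']
                  | NAME '{' expr [':' expr] '}'
                  | NAME
    rate_law     := 'MA' '(' expr ')' | [ 'UD' '(' ] NAME '(' args ')' [ ')' ]
    expr         := sum | arithmetic over numbers, names, calls, NAME '.' NAME
    sum          := 'SUM' '(' NAME (';' NAME '{' expr [':' expr] '}')* [';' expr] ')'

The circular-state flag is written ``~circ`` after the closing brace,
e.g. ``phase(s{0:3}~circ)``.
"""
from __future__ import annotations

from typing import List, Optional, Tuple, Union

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
from .lexer import LexError, Token, tokenize

_OPERATOR_KEYWORDS = ("succ", "pred")
_PARAM_ROLES = ("GLQ", "SITE", "SUB")

SECTION_NAMES = ("species", "reactions", "globals", "functions", "complexes", "initials")


class ParseError(ValueError):
    def __init__(self, message: str, line: int, col: int):
        super().__init__(f"{line}:{col}: {message}")
        self.message = message
        self.line = line
        self.col = col


class _Parser:
    def __init__(self, tokens: List[Token]):
        self.tokens = tokens
        self.pos = 0

    # -- token plumbing ----------------------------------------------------
    @property
    def cur(self) -> Token:
        return self.tokens[self.pos]

    def at(self, kind: str, value: Optional[str] = None) -> bool:
        t = self.cur
        return t.kind == kind and (value is None or t.value == value)

    def accept(self, kind: str, value: Optional[str] = None) -> Optional[Token]:
        if self.at(kind, value):
            t = self.cur
            self.pos += 1
            return t
        return None

    def expect(self, kind: str, value: Optional[str] = None) -> Token:
        t = self.accept(kind, value)
        if t is None:
            got = self.cur.value or self.cur.kind
            want = value if value is not None else kind
            raise ParseError(f"expected {want!r}, got {got!r}", self.cur.line, self.cur.col)
        return t

    def expect_eof(self) -> None:
        if not self.at("EOF"):
            raise ParseError(
                f"unexpected trailing input {self.cur.value!r}", self.cur.line, self.cur.col
            )

    def loc(self) -> Tuple[int, int]:
        return (self.cur.line, self.cur.col)

    # -- expressions -------------------------------------------------------
    def expression(self) -> Expr:
        node = self.term()
        while self.at("SYM", "+") or self.at("SYM", "-"):
            op = self.cur.value
            l = self.loc()
            self.pos += 1
            node = BinOp(op, node, self.term(), loc=l)
        return node

    def term(self) -> Expr:
        node = self.factor()
        while self.at("SYM", "*") or self.at("SYM", "/"):
            op = self.cur.value
            l = self.loc()
            self.pos += 1
            node = BinOp(op, node, self.factor(), loc=l)
        return node

    def factor(self) -> Expr:
        if self.at("SYM", "-"):
            l = self.loc()
            self.pos += 1
            return UnaryOp("-", self.factor(), loc=l)
        if self.at("SYM", "+"):
            self.pos += 1
            return self.factor()
        return self.power()

    def power(self) -> Expr:
        base = self.atom()
        if self.at("SYM", "^"):
            l = self.loc()
            self.pos += 1
            return BinOp("^", base, self.factor(), loc=l)  # right-associative
        return base

    def atom(self) -> Expr:
        t = self.cur
        if t.kind == "NUMBER":
            self.pos += 1
            value = float(t.value) if "." in t.value else int(t.value)
            return Num(value, loc=(t.line, t.col))
        if self.at("SYM", "("):
            self.pos += 1
            node = self.expression()
            self.expect("SYM", ")")
            return node
        if t.kind == "IDENT":
            self.pos += 1
            if t.value == "SUM" and self.at("SYM", "("):
                return self.sum_tail(t)
            if self.at("SYM", "("):
                self.pos += 1
                args: List[Expr] = []
                if not self.at("SYM", ")"):
                    args.append(self.expression())
                    while self.accept("SYM", ","):
                        args.append(self.expression())
                self.expect("SYM", ")")
                return Call(t.value, args, loc=(t.line, t.col))
            if self.at("SYM", "."):
                self.pos += 1
                site = self.expect("IDENT")
                return SiteAccess(t.value, site.value, loc=(t.line, t.col))
            return Name(t.value, loc=(t.line, t.col))
        raise ParseError(f"expected expression, got {t.value or t.kind!r}", t.line, t.col)

    def sum_tail(self, sum_tok: Token) -> SumNode:
        """Parse SUM(species; site{lo:hi}; ...; weight?) after 'SUM'."""
        self.expect("SYM", "(")
        species = self.expect("IDENT").value
        restrictions: List[Tuple[str, RangeExpr]] = []
        weight: Optional[Expr] = None
        while self.accept("SYM", ";"):
            # a segment of the form NAME '{' ... '}' is a site restriction;
            # anything else is the (final) weight expression
            if (
                self.at("IDENT")
                and self.tokens[self.pos + 1].kind == "SYM"
                and self.tokens[self.pos + 1].value == "{"
            ):
                site = self.expect("IDENT").value
                restrictions.append((site, self.brace_range()))
            else:
                if weight is not None:
                    raise ParseError("SUM allows a single weight segment", *self.loc())
                weight = self.expression()
        self.expect("SYM", ")")
        return SumNode(species, restrictions, weight, loc=(sum_tok.line, sum_tok.col))

    def brace_range(self) -> RangeExpr:
        """'{' expr [':' expr] '}' — single value becomes lo == hi."""
        l = self.loc()
        self.expect("SYM", "{")
        lo = self.expression()
        if self.accept("SYM", ":"):
            hi = self.expression()
        else:
            hi = lo
        self.expect("SYM", "}")
        return RangeExpr(lo, hi, loc=l)

    # -- species definitions ----------------------------------------------
    def species_def(self) -> SpeciesDefAST:
        name_tok = self.expect("IDENT")
        sites: List[SiteDefAST] = []
        if self.accept("SYM", "("):
            sites.append(self.site_def())
            while self.accept("SYM", ","):
                sites.append(self.site_def())
            self.expect("SYM", ")")
        seen = set()
        for s in sites:
            if s.name in seen:
                raise ParseError(f"duplicate site name {s.name!r}", *(s.loc or (0, 0)))
            seen.add(s.name)
        default_initial = None
        assignment = None
        if self.accept("ASSIGN"):
            assignment = self.expression()
        elif self.accept("SYM", "="):
            default_initial = self.expression()
        return SpeciesDefAST(
            name_tok.value,
            sites,
            default_initial=default_initial,
            assignment=assignment,
            loc=(name_tok.line, name_tok.col),
        )

    def site_def(self) -> SiteDefAST:
        name_tok = self.expect("IDENT")
        states: Optional[Union[RangeSpec, EnumSpec]] = None
        if self.at("SYM", "{"):
            states = self.state_list()
        circular = False
        if self.accept("SYM", "~"):
            flag = self.expect("IDENT")
            if flag.value != "circ":
                raise ParseError(f"unknown site flag {flag.value!r}", flag.line, flag.col)
            circular = True
        return SiteDefAST(name_tok.value, states, circular, loc=(name_tok.line, name_tok.col))

    def state_list(self) -> Union[RangeSpec, EnumSpec]:
        l = self.loc()
        self.expect("SYM", "{")
        if self.at("SYM", "}"):
            raise ParseError("empty state list", *self.loc())
        first = self.expression()
        if self.accept("SYM", ":"):
            hi = self.expression()
            self.expect("SYM", "}")
            return RangeSpec(first, hi, loc=l)
        labels = [self._expr_to_label(first)]
        while self.accept("SYM", ","):
            labels.append(self._expr_to_label(self.expression()))
        self.expect("SYM", "}")
        if len(labels) != len(set(labels)):
            raise ParseError("duplicate state label in enumeration", *l)
        return EnumSpec(labels, loc=l)

    @staticmethod
    def _expr_to_label(e: Expr) -> Union[int, str]:
        if isinstance(e, Num) and float(e.value) == int(e.value):
            return int(e.value)
        if isinstance(e, Name):
            return e.ident
        loc = getattr(e, "loc", None) or (0, 0)
        raise ParseError("state labels must be integers or identifiers", *loc)

    # -- species references / patterns --------------------------------------
    def species_ref(self) -> SpeciesRefAST:
        name_tok = self.expect("IDENT")
        patterns: List[Tuple[str, Pattern]] = []
        if self.accept("SYM", "("):
            patterns.append(self.pattern())
            while self.accept("SYM", ","):
                patterns.append(self.pattern())
            self.expect("SYM", ")")
        seen = set()
        for site, _ in patterns:
            if site in seen:
                raise ParseError(
                    f"more than one pattern for site {site!r}", name_tok.line, name_tok.col
                )
            seen.add(site)
        return SpeciesRefAST(name_tok.value, patterns, loc=(name_tok.line, name_tok.col))

    def pattern(self) -> Tuple[str, Pattern]:
        t = self.expect("IDENT")
        l = (t.line, t.col)
        if t.value in _OPERATOR_KEYWORDS and self.at("SYM", "("):
            self.pos += 1
            site = self.expect("IDENT").value
            self.expect("SYM", ")")
            return site, OpCall(t.value, site, loc=l)
        if self.accept("SYM", "="):
            return t.value, self.transfer_rhs(l)
        if self.at("SYM", "{"):
            r = self.brace_range()
            if r.lo is r.hi:  # single value {x}
                return t.value, FixedState(r.lo, loc=l)
            return t.value, RangePattern(r.lo, r.hi, loc=l)
        return t.value, RangePattern(None, None, loc=l)  # bare site: full range

    def transfer_rhs(self, l: Tuple[int, int]) -> Transfer:
        t = self.expect("IDENT")
        op: Optional[str] = None
        if t.value in _OPERATOR_KEYWORDS and self.at("SYM", "("):
            op = t.value
            self.pos += 1
            t = self.expect("IDENT")
        self.expect("SYM", ".")
        src_site = self.expect("IDENT").value
        if op is not None:
            self.expect("SYM", ")")
        return Transfer(t.value, src_site, op, loc=l)

    # -- reactions -----------------------------------------------------------
    def reaction(self) -> ReactionAST:
        l = self.loc()
        reactants: List[SpeciesRefAST] = []
        if not self.at("ARROW"):
            reactants.append(self.species_ref())
            while self.accept("SYM", "+"):
                reactants.append(self.species_ref())
        self.expect("ARROW")
        products: List[SpeciesRefAST] = []
        if not (self.at("EOF") or self.at("SYM", ";") or self.at("SYM", ":")):
            products.append(self.species_ref())
            while self.accept("SYM", "+"):
                products.append(self.species_ref())
        modifiers: List[SpeciesRefAST] = []
        if self.accept("SYM", ";"):
            modifiers.append(self.species_ref())
            while self.accept("SYM", ","):
                modifiers.append(self.species_ref())
        rate_law = None
        if self.accept("SYM", ":"):
            rate_law = self.rate_law()
        for ref in reactants:
            for site, pat in ref.site_patterns:
                if isinstance(pat, (OpCall, Transfer)):
                    raise ParseError(
                        f"operator pattern on site {site!r} is not allowed in reactants",
                        *(pat.loc or l),
                    )
        return ReactionAST(reactants, products, modifiers, rate_law, loc=l)

    def rate_law(self):
        t = self.expect("IDENT")
        l = (t.line, t.col)
        if t.value == "MA":
            self.expect("SYM", "(")
            rate = self.expression()
            self.expect("SYM", ")")
            return MassActionLaw(rate, loc=l)
        if t.value == "KIN":
            self.expect("SYM", "(")
            expr = self.expression()
            self.expect("SYM", ")")
            return RawKineticLaw(expr, loc=l)
        if t.value == "UD":
            self.expect("SYM", "(")
            inner = self.expect("IDENT")
            call = self._call_args(inner)
            self.expect("SYM", ")")
            return UserDefinedLaw(call.func, call.args, loc=l)
        call = self._call_args(t)
        return UserDefinedLaw(call.func, call.args, loc=l)

    def _call_args(self, name_tok: Token) -> Call:
        self.expect("SYM", "(")
        args: List[Expr] = []
        if not self.at("SYM", ")"):
            args.append(self.expression())
            while self.accept("SYM", ","):
                args.append(self.expression())
        self.expect("SYM", ")")
        return Call(name_tok.value, args, loc=(name_tok.line, name_tok.col))

    # -- other sections -------------------------------------------------------
    def global_def(self) -> GlobalQuantityAST:
        name_tok = self.expect("IDENT")
        if self.accept("ASSIGN"):
            role = "assigned"
        else:
            self.expect("SYM", "=")
            role = "fixed"
        expr = self.expression()
        return GlobalQuantityAST(name_tok.value, role, expr, loc=(name_tok.line, name_tok.col))

    def function_def(self) -> FunctionDefAST:
        name_tok = self.expect("IDENT")
        self.expect("SYM", "(")
        params: List[Tuple[str, str]] = []
        if not self.at("SYM", ")"):
            params.append(self._param())
            while self.accept("SYM", ","):
                params.append(self._param())
        self.expect("SYM", ")")
        self.expect("SYM", "=")
        body = self.expression()
        return FunctionDefAST(name_tok.value, params, body, loc=(name_tok.line, name_tok.col))

    def _param(self) -> Tuple[str, str]:
        role_tok = self.expect("IDENT")
        if role_tok.value not in _PARAM_ROLES:
            raise ParseError(
                f"parameter role must be one of {_PARAM_ROLES}, got {role_tok.value!r}",
                role_tok.line,
                role_tok.col,
            )
        name_tok = self.expect("IDENT")
        return (name_tok.value, role_tok.value)

    def complex_def(self) -> ComplexDefAST:
        l = self.loc()
        name: Optional[str] = None
        # lookahead for 'NAME =' prefix (explicit complex name)
        if (
            self.at("IDENT")
            and self.tokens[self.pos + 1].kind == "SYM"
            and self.tokens[self.pos + 1].value == "="
        ):
            name = self.expect("IDENT").value
            self.expect("SYM", "=")
        components = [self._component()]
        while self.accept("SYM", "+"):
            components.append(self._component())
        generate = False
        if self.accept("SYM", "~"):
            flag = self.expect("IDENT")
            if flag.value != "reactions":
                raise ParseError(f"unknown complex flag {flag.value!r}", flag.line, flag.col)
            generate = True
        return ComplexDefAST(name, components, generate, loc=l)

    def _component(self) -> ComplexComponentAST:
        name_tok = self.expect("IDENT")
        tracked: List[Tuple[str, Optional[RangeExpr]]] = []
        if self.accept("SYM", "("):
            while True:
                site = self.expect("IDENT").value
                restriction = self.brace_range() if self.at("SYM", "{") else None
                tracked.append((site, restriction))
                if not self.accept("SYM", ","):
                    break
            self.expect("SYM", ")")
        return ComplexComponentAST(name_tok.value, tracked, loc=(name_tok.line, name_tok.col))

    def state_initial(self) -> StateInitialAST:
        name_tok = self.expect("IDENT")
        self.expect("SYM", "(")
        assignment: List[Tuple[str, Union[int, str]]] = []
        while True:
            site = self.expect("IDENT").value
            self.expect("SYM", "{")
            label = self._expr_to_label(self.expression())
            self.expect("SYM", "}")
            assignment.append((site, label))
            if not self.accept("SYM", ","):
                break
        self.expect("SYM", ")")
        self.expect("SYM", "=")
        value = self.expression()
        return StateInitialAST(
            name_tok.value, assignment, value, loc=(name_tok.line, name_tok.col)
        )


# ---------------------------------------------------------------------------
# Public entry points
# ---------------------------------------------------------------------------

def _parse_one(text: str, method: str, line_offset: int = 1):
    p = _Parser(tokenize(text, line_offset))
    node = getattr(p, method)()
    p.expect_eof()
    return node


def parse_species(text: str) -> SpeciesDefAST:
    """Parse a single species definition, e.g. ``Cdh1(p{0:10})``."""
    return _parse_one(text, "species_def")


def parse_reaction(text: str) -> ReactionAST:
    """Parse a single reaction, e.g. ``Cdh1(p{0:9}) + ClbM -> Cdh1(succ(p)) + ClbM``."""
    return _parse_one(text, "reaction")


def parse_expression(text: str) -> Expr:
    """Parse an arithmetic expression, possibly containing SUM and accessors."""
    return _parse_one(text, "expression")


_SECTION_METHODS = {
    "species": ("species", "species_def"),
    "reactions": ("reactions", "reaction"),
    "globals": ("globals", "global_def"),
    "functions": ("functions", "function_def"),
    "complexes": ("complexes", "complex_def"),
    "initials": ("initials", "state_initial"),
}


def parse_model(document: str) -> Tuple[ModelAST, List[ValidationIssue]]:
    """Parse a sectioned ``.msl`` document.

    Parse errors are collected per entry line — a malformed entry becomes a
    diagnostic and parsing continues, so a document saved with errors can
    always be read back.
    """
    ast = ModelAST()
    diags: List[ValidationIssue] = []
    section: Optional[str] = None
    for lineno, raw in enumerate(document.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        header = line[:-1].strip().lower() if line.endswith(":") else None
        if header in SECTION_NAMES:
            section = header
            continue
        if section is None:
            diags.append(
                ValidationIssue(
                    Severity.ERROR,
                    "no-section",
                    f"entry before any section header: {line!r}",
                    (lineno, 1),
                )
            )
            continue
        attr, method = _SECTION_METHODS[section]
        try:
            node = _parse_one(raw.split("#", 1)[0], method, line_offset=lineno)
        except (ParseError, LexError) as exc:
            diags.append(
                ValidationIssue(
                    Severity.ERROR,
                    "parse-error",
                    f"in section {section!r}: {exc.message}",
                    (exc.line, exc.col),
                )
            )
            continue
        getattr(ast, attr).append(node)
    return ast, diags
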