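"""SBML Level 3 Version 1 (core) export of a flat model.

Mapping: every flat species becomes an SBML species in a single default
compartment of size 1; fixed globals become constant parameters;
SUM-derived quantities and per-instance modifier species become
assignment rules; every flat reaction becomes an irreversible reaction
with its grounded kinetic law as content MathML. Names that are not
legal SBML SIds (e.g. ``80S``, which starts with a digit) are sanitized
deterministically — an underscore prefix, plus numeric suffixing on
collision — and the original name is preserved in the ``name`` attribute.

:func:`check_sbml` is a structural consistency checker for the documents
this module produces: SId syntax and uniqueness, reference resolution
(compartments, species, parameters, rule variables, every ``<ci>`` in
math), rule-variable constraints, and MathML arity. It returns a list of
error strings; an empty list means the document is consistent.
"""
from __future__ import annotations

import re
import xml.etree.ElementTree as ET
from typing import Dict, List, Optional

from ._ast import BinOp, Call, Expr, Name, Num, SiteAccess, UnaryOp
from .expand import FlatModel

SBML_NS = "http://www.sbml.org/sbml/level3/version1/core"
MATHML_NS = "http://www.w3.org/1998/Math/MathML"

_SID_RE = re.compile(r"^[A-Za-z_][A-Za-z0-9_]*$")
_COMPARTMENT_ID = "cell"


def sanitize_id(name: str, taken: Dict[str, str]) -> str:
    """Deterministically map *name* to a fresh legal SId."""
    sid = name if _SID_RE.match(name) else "_" + re.sub(r"[^A-Za-z0-9_]", "_", name)
    if not _SID_RE.match(sid):  # still broken (e.g. empty)
        sid = "_x"
    base = sid
    n = 1
    while sid in taken.values():
        n += 1
        sid = f"{base}_{n}"
    return sid


def _math_element(expr: Expr, sid_of: Dict[str, str]) -> ET.Element:
    math = ET.Element(f"{{{MATHML_NS}}}math")
    math.append(_math_node(expr, sid_of))
    return math


def _math_node(expr: Expr, sid_of: Dict[str, str]) -> ET.Element:
    if isinstance(expr, Num):
        cn = ET.Element(f"{{{MATHML_NS}}}cn")
        if float(expr.value) == int(expr.value):
            cn.set("type", "integer")
            cn.text = str(int(expr.value))
        else:
            cn.text = repr(float(expr.value))
        return cn
    if isinstance(expr, Name):
        ci = ET.Element(f"{{{MATHML_NS}}}ci")
        ci.text = sid_of.get(expr.ident, expr.ident)
        return ci
    if isinstance(expr, UnaryOp):
        apply_ = ET.Element(f"{{{MATHML_NS}}}apply")
        apply_.append(ET.Element(f"{{{MATHML_NS}}}minus"))
        apply_.append(_math_node(expr.operand, sid_of))
        return apply_
    if isinstance(expr, BinOp):
        ops = {"+": "plus", "-": "minus", "*": "times", "/": "divide", "^": "power"}
        apply_ = ET.Element(f"{{{MATHML_NS}}}apply")
        apply_.append(ET.Element(f"{{{MATHML_NS}}}{ops[expr.op]}"))
        apply_.append(_math_node(expr.left, sid_of))
        apply_.append(_math_node(expr.right, sid_of))
        return apply_
    if isinstance(expr, SiteAccess):
        raise ValueError(
            f"kinetic expression still contains site accessor "
            f"{expr.species}.{expr.site}; the model was not fully grounded"
        )
    if isinstance(expr, Call):
        raise ValueError(
            f"kinetic expression still contains a call to {expr.func!r}; "
            "function calls are instantiated before export"
        )
    raise ValueError(f"cannot export {type(expr).__name__} to MathML")


def write_sbml(flat: FlatModel, model_id: str = "model") -> str:
    """Serialize *flat* as an SBML Level 3 Version 1 document (XML text)."""
    ET.register_namespace("", SBML_NS)
    ET.register_namespace("math", MATHML_NS)
    sbml = ET.Element(f"{{{SBML_NS}}}sbml", {"level": "3", "version": "1"})
    model = ET.SubElement(sbml, f"{{{SBML_NS}}}model", {"id": model_id})

    sid_of: Dict[str, str] = {}
    rule_targets = {target for target, _ in flat.assignment_rules}

    comps = ET.SubElement(model, f"{{{SBML_NS}}}listOfCompartments")
    ET.SubElement(
        comps,
        f"{{{SBML_NS}}}compartment",
        {"id": _COMPARTMENT_ID, "size": "1", "constant": "true", "spatialDimensions": "3"},
    )

    if flat.species:
        lst = ET.SubElement(model, f"{{{SBML_NS}}}listOfSpecies")
        for sp in flat.species:
            sid = sanitize_id(sp.name, sid_of)
            sid_of[sp.name] = sid
            attrs = {
                "id": sid,
                "name": sp.name,
                "compartment": _COMPARTMENT_ID,
                "hasOnlySubstanceUnits": "true",
                "boundaryCondition": "false",
                "constant": "false",
            }
            if sp.name not in rule_targets:
                attrs["initialAmount"] = _fmt(sp.initial)
            ET.SubElement(lst, f"{{{SBML_NS}}}species", attrs)

    if flat.parameters or rule_targets:
        lst = ET.SubElement(model, f"{{{SBML_NS}}}listOfParameters")
        for pname, value in flat.parameters.items():
            sid = sanitize_id(pname, sid_of)
            sid_of[pname] = sid
            ET.SubElement(
                lst,
                f"{{{SBML_NS}}}parameter",
                {"id": sid, "name": pname, "value": _fmt(value), "constant": "true"},
            )
        for target, _ in flat.assignment_rules:
            if target in sid_of:  # species target already declared
                continue
            sid = sanitize_id(target, sid_of)
            sid_of[target] = sid
            ET.SubElement(
                lst,
                f"{{{SBML_NS}}}parameter",
                {"id": sid, "name": target, "constant": "false"},
            )

    if flat.assignment_rules:
        lst = ET.SubElement(model, f"{{{SBML_NS}}}listOfRules")
        for target, expr in flat.assignment_rules:
            rule = ET.SubElement(
                lst, f"{{{SBML_NS}}}assignmentRule", {"variable": sid_of[target]}
            )
            rule.append(_math_element(expr, sid_of))

    if flat.reactions:
        lst = ET.SubElement(model, f"{{{SBML_NS}}}listOfReactions")
        for rxn in flat.reactions:
            rid = sanitize_id(rxn.name, sid_of)
            sid_of[rxn.name] = rid
            relem = ET.SubElement(
                lst,
                f"{{{SBML_NS}}}reaction",
                # 'fast' is required in L3V1 (it was dropped only in L3V2)
                {"id": rid, "reversible": "false", "fast": "false"},
            )
            for tag, participants in (
                ("listOfReactants", rxn.reactants),
                ("listOfProducts", rxn.products),
            ):
                if not participants:
                    continue
                plist = ET.SubElement(relem, f"{{{SBML_NS}}}{tag}")
                counts: Dict[str, int] = {}
                for p in participants:  # stoichiometry by repetition
                    counts[p] = counts.get(p, 0) + 1
                for p, count in counts.items():
                    ET.SubElement(
                        plist,
                        f"{{{SBML_NS}}}speciesReference",
                        {
                            "species": sid_of[p],
                            "stoichiometry": str(count),
                            "constant": "true",
                        },
                    )
            if rxn.modifiers:
                mlist = ET.SubElement(relem, f"{{{SBML_NS}}}listOfModifiers")
                for mname in dict.fromkeys(rxn.modifiers):
                    ET.SubElement(
                        mlist,
                        f"{{{SBML_NS}}}modifierSpeciesReference",
                        {"species": sid_of[mname]},
                    )
            if rxn.kinetic is not None:
                klaw = ET.SubElement(relem, f"{{{SBML_NS}}}kineticLaw")
                klaw.append(_math_element(rxn.kinetic, sid_of))

    ET.indent(sbml)
    return '<?xml version="1.0" encoding="UTF-8"?>\n' + ET.tostring(
        sbml, encoding="unicode"
    )


def _fmt(value: float) -> str:
    if float(value) == int(value):
        return str(int(value))
    return repr(float(value))


# ---------------------------------------------------------------------------
# structural consistency checking
# ---------------------------------------------------------------------------

def check_sbml(document: str) -> List[str]:
    """Check an SBML L3V1 document for structural consistency.

    Returns a list of human-readable error strings (empty = consistent).
    """
    problems: List[str] = []
    try:
        root = ET.fromstring(document)
    except ET.ParseError as exc:
        return [f"XML parse error: {exc}"]
    if root.tag != f"{{{SBML_NS}}}sbml":
        problems.append(f"root element is {root.tag}, not sbml (L3V1 namespace)")
        return problems
    if root.get("level") != "3" or root.get("version") != "1":
        problems.append("sbml element must declare level=3 version=1")
    model = root.find(f"{{{SBML_NS}}}model")
    if model is None:
        problems.append("missing <model> element")
        return problems

    def findall(parent, list_tag, item_tag):
        lst = parent.find(f"{{{SBML_NS}}}{list_tag}")
        return [] if lst is None else lst.findall(f"{{{SBML_NS}}}{item_tag}")

    ids: Dict[str, str] = {}  # sid -> kind

    def declare(elem, kind) -> Optional[str]:
        sid = elem.get("id")
        if sid is None:
            problems.append(f"{kind} without an id")
            return None
        if not _SID_RE.match(sid):
            problems.append(f"{kind} id {sid!r} is not a legal SId")
        if sid in ids:
            problems.append(f"duplicate SId {sid!r} ({ids[sid]} and {kind})")
        ids[sid] = kind
        return sid

    compartments = findall(model, "listOfCompartments", "compartment")
    for c in compartments:
        declare(c, "compartment")
    species = findall(model, "listOfSpecies", "species")
    for s in species:
        declare(s, "species")
        comp = s.get("compartment")
        if comp is None or ids.get(comp) != "compartment":
            problems.append(
                f"species {s.get('id')!r} references unknown compartment {comp!r}"
            )
        for attr in ("hasOnlySubstanceUnits", "boundaryCondition", "constant"):
            if s.get(attr) not in ("true", "false"):
                problems.append(f"species {s.get('id')!r} missing required flag {attr}")
    parameters = findall(model, "listOfParameters", "parameter")
    for p in parameters:
        declare(p, "parameter")
        if p.get("constant") not in ("true", "false"):
            problems.append(f"parameter {p.get('id')!r} missing required flag constant")

    def check_math(math: Optional[ET.Element], where: str) -> None:
        if math is None:
            problems.append(f"{where}: missing <math>")
            return
        children = list(math)
        if len(children) != 1:
            problems.append(f"{where}: <math> must contain exactly one expression")
            return
        _check_math_node(children[0], where, ids, problems)

    rule_variables: List[str] = []
    for rule in findall(model, "listOfRules", "assignmentRule"):
        var = rule.get("variable")
        if var is None or ids.get(var) not in ("species", "parameter", "compartment"):
            problems.append(f"assignmentRule variable {var!r} does not resolve")
        else:
            rule_variables.append(var)
            holder = next(
                e
                for e in species + parameters + compartments
                if e.get("id") == var
            )
            if holder.get("constant") == "true":
                problems.append(f"assignmentRule variable {var!r} is declared constant")
        check_math(rule.find(f"{{{MATHML_NS}}}math"), f"rule for {var!r}")
    if len(rule_variables) != len(set(rule_variables)):
        problems.append("more than one assignmentRule for the same variable")

    in_flux: set = set()
    for rxn in findall(model, "listOfReactions", "reaction"):
        rid = declare(rxn, "reaction")
        for attr in ("reversible", "fast"):
            if rxn.get(attr) not in ("true", "false"):
                problems.append(f"reaction {rid!r} missing required flag {attr}")
        for tag in ("listOfReactants", "listOfProducts"):
            for ref in findall(rxn, tag, "speciesReference"):
                target = ref.get("species")
                if ids.get(target) != "species":
                    problems.append(
                        f"reaction {rid!r}: speciesReference to unknown species "
                        f"{target!r}"
                    )
                else:
                    in_flux.add(target)
                if ref.get("constant") not in ("true", "false"):
                    problems.append(
                        f"reaction {rid!r}: speciesReference missing flag constant"
                    )
        for ref in findall(rxn, "listOfModifiers", "modifierSpeciesReference"):
            if ids.get(ref.get("species")) != "species":
                problems.append(
                    f"reaction {rid!r}: modifier references unknown species "
                    f"{ref.get('species')!r}"
                )
        klaw = rxn.find(f"{{{SBML_NS}}}kineticLaw")
        if klaw is not None:
            check_math(klaw.find(f"{{{MATHML_NS}}}math"), f"kinetic law of {rid!r}")

    # a species governed by an assignment rule must not also be produced or
    # consumed by reactions (its amount is determined by the rule alone)
    for var in rule_variables:
        if ids.get(var) == "species" and var in in_flux:
            problems.append(
                f"species {var!r} is both an assignmentRule target and a "
                "reactant/product"
            )
    return problems


_MATHML_OPS = {"plus", "minus", "times", "divide", "power"}


def _check_math_node(node: ET.Element, where: str, ids: Dict[str, str], problems: List[str]):
    tag = node.tag.removeprefix(f"{{{MATHML_NS}}}")
    if tag == "cn":
        try:
            float(node.text or "")
        except ValueError:
            problems.append(f"{where}: <cn> is not numeric: {node.text!r}")
        return
    if tag == "ci":
        ident = (node.text or "").strip()
        if ident not in ids:
            problems.append(f"{where}: <ci>{ident}</ci> does not resolve to any SId")
        return
    if tag == "apply":
        children = list(node)
        if not children:
            problems.append(f"{where}: empty <apply>")
            return
        op = children[0].tag.removeprefix(f"{{{MATHML_NS}}}")
        if op not in _MATHML_OPS:
            problems.append(f"{where}: unsupported MathML operator {op!r}")
            return
        argc = len(children) - 1
        if op == "minus" and argc not in (1, 2):
            problems.append(f"{where}: minus takes 1 or 2 arguments, got {argc}")
        elif op in ("divide", "power") and argc != 2:
            problems.append(f"{where}: {op} takes 2 arguments, got {argc}")
        elif op in ("plus", "times") and argc < 1:
            problems.append(f"{where}: {op} needs at least one argument")
        for child in children[1:]:
            _check_math_node(child, where, ids, problems)
        return
    problems.append(f"{where}: unexpected MathML element {tag!r}")
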