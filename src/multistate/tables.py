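"""Flat CSV tables, model statistics, and the flat ``.msl`` dialect.

CSV dialect: comma-separated, UTF-8, header row, quoting only where
needed (pandas defaults) — deterministic column and row order so two
exports of the same model are byte-identical.
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Dict

import pandas as pd

from .expand import FlatModel
from .model import Model
from .unparse import unparse_expr

SPECIES_COLUMNS = ["name", "base_species", "state", "initial_amount"]
REACTION_COLUMNS = ["name", "reaction", "kinetic_law"]
PARAMETER_COLUMNS = ["name", "value", "kind"]


def species_frame(flat: FlatModel) -> pd.DataFrame:
    rows = [
        {
            "name": sp.name,
            "base_species": sp.base,
            "state": ";".join(f"{site}={label}" for site, label in sp.assignment),
            "initial_amount": sp.initial,
        }
        for sp in flat.species
    ]
    return pd.DataFrame(rows, columns=SPECIES_COLUMNS)


def reactions_frame(flat: FlatModel) -> pd.DataFrame:
    rows = [
        {
            "name": rxn.name,
            "reaction": rxn.reaction_string(),
            "kinetic_law": unparse_expr(rxn.kinetic) if rxn.kinetic is not None else "",
        }
        for rxn in flat.reactions
    ]
    return pd.DataFrame(rows, columns=REACTION_COLUMNS)


def parameters_frame(flat: FlatModel) -> pd.DataFrame:
    rows = [
        {"name": name, "value": value, "kind": "parameter"}
        for name, value in flat.parameters.items()
    ]
    rows += [
        {"name": target, "value": unparse_expr(expr), "kind": "assignment"}
        for target, expr in flat.assignment_rules
    ]
    return pd.DataFrame(rows, columns=PARAMETER_COLUMNS)


def write_tables(flat: FlatModel, outdir) -> Dict[str, Path]:
    """Write species.csv, reactions.csv and parameters.csv under *outdir*."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, frame in (
        ("species", species_frame(flat)),
        ("reactions", reactions_frame(flat)),
        ("parameters", parameters_frame(flat)),
    ):
        path = outdir / f"{name}.csv"
        frame.to_csv(path, index=False)
        paths[name] = path
    return paths


def read_tables(outdir) -> Dict[str, pd.DataFrame]:
    outdir = Path(outdir)
    return {
        name: pd.read_csv(outdir / f"{name}.csv", keep_default_na=False)
        for name in ("species", "reactions", "parameters")
    }


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelStats:
    """Compact-vs-flat size of a model.

    The reduction fraction ``1 - compact/flat`` measures how much smaller
    the multistate representation is than its single-state expansion (per
    category); it is 0 for a model with no multistate constructs.
    """

    compact_species: int
    compact_reactions: int
    flat_species: int
    flat_reactions: int
    species_reduction: float
    reaction_reduction: float

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2)


def model_stats(model: Model, flat: FlatModel) -> ModelStats:
    cs = len(model.species)
    cr = len(model.reactions)
    fs = len(flat.species)
    fr = len(flat.reactions)
    return ModelStats(
        compact_species=cs,
        compact_reactions=cr,
        flat_species=fs,
        flat_reactions=fr,
        species_reduction=(1 - cs / fs) if fs else 0.0,
        reaction_reduction=(1 - cr / fr) if fr else 0.0,
    )


# ---------------------------------------------------------------------------
# flat .msl dialect
# ---------------------------------------------------------------------------

def flat_to_msl(flat: FlatModel) -> str:
    """Serialize a flat model in the ``.msl`` dialect without multistate
    constructs: plain species, ``KIN(...)`` kinetic expressions, fixed
    globals, and assignment rules as ``:=`` entries."""
    out = []
    rule_targets = {t for t, _ in flat.assignment_rules}
    species_names = {sp.name for sp in flat.species}
    out.append("species:")
    for sp in flat.species:
        if sp.name in rule_targets:
            expr = next(e for t, e in flat.assignment_rules if t == sp.name)
            out.append(f"{sp.name} := {unparse_expr(expr)}")
        else:
            out.append(f"{sp.name} = {_fmt(sp.initial)}")
    out.append("")
    if flat.reactions:
        out.append("reactions:")
        for rxn in flat.reactions:
            line = rxn.reaction_string()
            if rxn.kinetic is not None:
                line += f" : KIN({unparse_expr(rxn.kinetic)})"
            out.append(line)
        out.append("")
    if flat.parameters or any(t not in species_names for t in rule_targets):
        out.append("globals:")
        for name, value in flat.parameters.items():
            out.append(f"{name} = {_fmt(value)}")
        for target, expr in flat.assignment_rules:
            if target not in species_names:
                out.append(f"{target} := {unparse_expr(expr)}")
        out.append("")
    return "\n".join(out)


def _fmt(value: float) -> str:
    if float(value) == int(value):
        return str(int(value))
    return repr(float(value))
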