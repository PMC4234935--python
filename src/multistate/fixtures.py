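"""Reference models built programmatically, with checked-in golden files.

Each builder writes the model in the ``.msl`` language and loads it, so
the fixtures exercise the full parse -> build path and round-trip through
the serializer by construction. Rate constants and initial amounts are
plausible placeholders (all 1 or 0): the originals' full kinetic
parameterizations are not part of these reconstructions, and none of the
structural counts depend on them.

* :func:`cdh1_toy` — a protein with a chain of phosphorylation states
  (one site ``p`` ranging 0..maxP), phosphorylated by a kinase via the
  successor operator and dephosphorylated via the predecessor, plus a
  SUM-defined total of its phosphorylated forms. At maxP=10 this is the
  two-collective-reaction system that expands to 20 single-state
  reactions over 11 forms.
* :func:`xp_phosphorylation` — distributive multisite phosphorylation of
  a substrate XP by a kinase, as one multistate reaction; ``ordered``
  uses plain mass action, ``disordered`` a user-defined law whose rate
  coefficient (N - i)*k falls with the number of already-phosphorylated
  sites. Switching mechanism changes only the rate law.
* :func:`translation_toy` — ribosomes (R) moving codon by codon along an
  mRNA: transfer-of-state products (the new position is succ of the old)
  and a per-instance modifier M whose assignment sums the ribosome
  occupancy in a moving window downstream of the current position. The
  window is clipped at the chain end. Scaling the mRNA from 20 to 300
  codons is a single global-quantity change.
* :func:`nonconsecutive_demo` — symbolic states (free/bound/hidden) and
  nonconsecutive integer states ({2,4,6,8,0}, where succ(2)=4) on one
  species, exercising order-based (not value-based) state operators.
"""
from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Callable, Dict

from .issues import errors
from .model import Model, load_model


def _load(text: str) -> Model:
    model, issues = load_model(text, autocompletion_policy="off")
    errs = errors(issues)
    if errs:  # fixtures must be clean by construction
        raise AssertionError(f"fixture failed to build: {[str(e) for e in errs]}")
    return model


def cdh1_toy_msl(maxP: int = 10) -> str:
    if maxP < 1:
        raise ValueError("maxP must be >= 1")
    return f"""\
species:
Cdh1(p{{0:maxP}}) = 1
ClbM = 1

reactions:
Cdh1(p{{0:maxP-1}}) + ClbM -> Cdh1(succ(p)) + ClbM : MA(kphos)
Cdh1(p{{1:maxP}}) -> Cdh1(pred(p)) : MA(kdeph)

globals:
maxP = {maxP}
kphos = 1
kdeph = 1
Cdh1T := SUM(Cdh1;p{{1:maxP}})
"""


def cdh1_toy(maxP: int = 10) -> Model:
    """Phosphorylation/dephosphorylation chain: 2 collective reactions
    expanding to 2*maxP flat reactions over maxP+1 forms of Cdh1."""
    return _load(cdh1_toy_msl(maxP))


def xp_phosphorylation_msl(N: int = 5, mechanism: str = "ordered") -> str:
    if N < 1:
        raise ValueError("N must be >= 1")
    if mechanism == "ordered":
        law = "MA(k)"
    elif mechanism == "disordered":
        law = "UD(dis(N, XP.i, k, XP, Kin))"
    else:
        raise ValueError(f"mechanism must be 'ordered' or 'disordered', got {mechanism!r}")
    return f"""\
species:
XP(i{{0:N}}) = 1
Kin = 1

reactions:
XP(i{{0:N-1}}) + Kin -> XP(succ(i)) + Kin : {law}

globals:
N = {N}
k = 1

functions:
dis(GLQ N, SITE i, GLQ k, SUB X, SUB K) = (N-i)*k*X*K
"""


def xp_phosphorylation(N: int = 5, mechanism: str = "ordered") -> Model:
    """Distributive multisite phosphorylation; the two mechanisms share
    the reaction graph and differ only in the kinetic formulas."""
    return _load(xp_phosphorylation_msl(N, mechanism))


def translation_toy_msl(length: int = 20, d: int = 3, window: int = 14) -> str:
    if not (1 <= d < length):
        raise ValueError("need 1 <= d < length")
    return f"""\
species:
R(c{{1:len}}) = 1
P1(c{{1:len}}) = 0
P2 = 0
M(c) := SUM(R;c{{M.c+1:M.c+w}})

reactions:
R(c{{1:d}}) -> P1(c=succ(R.c)) + P2 ; M(c=R.c) : MA(ktrans)

globals:
len = {length}
d = {d}
w = {window}
ktrans = 1
"""


def translation_toy(length: int = 20, d: int = 3, window: int = 14) -> Model:
    """mRNA translation-window toy: transfer-of-state movement along the
    chain and a moving-window SUM modifier, one flat reaction per codon
    in 1..d."""
    return _load(translation_toy_msl(length, d, window))


def nonconsecutive_demo_msl() -> str:
    return """\
species:
Demo(s1{free,bound,hidden}, s2{2,4,6,8,0}) = 1

reactions:
Demo(s1{free}, s2{2}) -> Demo(succ(s1), succ(s2)) : MA(kd)

globals:
kd = 1
"""


def nonconsecutive_demo() -> Model:
    """Symbolic and nonconsecutive integer state lists; 3x5 = 15 forms."""
    return _load(nonconsecutive_demo_msl())


@dataclass(frozen=True)
class FixtureSpec:
    name: str
    builder: Callable[..., Model]
    msl: Callable[..., str]


FIXTURES: Dict[str, FixtureSpec] = {
    "cdh1_toy": FixtureSpec("cdh1_toy", cdh1_toy, cdh1_toy_msl),
    "xp_ordered": FixtureSpec(
        "xp_ordered",
        lambda **kw: xp_phosphorylation(mechanism="ordered", **kw),
        lambda **kw: xp_phosphorylation_msl(mechanism="ordered", **kw),
    ),
    "xp_disordered": FixtureSpec(
        "xp_disordered",
        lambda **kw: xp_phosphorylation(mechanism="disordered", **kw),
        lambda **kw: xp_phosphorylation_msl(mechanism="disordered", **kw),
    ),
    "translation_toy": FixtureSpec("translation_toy", translation_toy, translation_toy_msl),
    "nonconsecutive_demo": FixtureSpec(
        "nonconsecutive_demo",
        lambda: nonconsecutive_demo(),
        lambda: nonconsecutive_demo_msl(),
    ),
}


def example_text(name: str) -> str:
    """The checked-in golden ``.msl`` file for fixture *name*."""
    return (
        resources.files("multistate").joinpath(f"examples/{name}.msl").read_text("utf-8")
    )
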