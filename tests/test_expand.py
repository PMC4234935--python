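"""Expansion: state lists, operators, instances, reactions, SUM, rate laws.

The random-model test checks the expander against an independent
brute-force enumerator that tries every full state combination and
filters by pattern membership, computing successor/predecessor by
integer arithmetic instead of list order (the two agree on consecutive
integer ranges, which is what the generator emits).
"""
import itertools
import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from multistate import fixtures
from multistate._ast import BinOp, Name, Num
from multistate.expand import (
    ExpansionError,
    enumerate_instances,
    expand_model,
    expand_reaction,
    expand_sum,
)
from multistate.issues import errors
from multistate.model import load_model, validate
from multistate.parser import parse_expression, parse_species
from multistate.states import (
    StateList,
    StateOrderError,
    predecessor,
    resolve_state_list,
    successor,
)
from multistate.unparse import unparse_expr


def load_clean(doc):
    model, issues = load_model(doc, autocompletion_policy="off")
    assert errors(issues) == [], [str(i) for i in issues]
    return model


class TestStateLists:
    def test_integer_range_inclusive(self):
        site = parse_species("Cdh1(p{0:10})").sites[0]
        states = resolve_state_list(site)
        assert list(states.labels) == list(range(11))

    def test_symbolic_bounds_resolve_through_globals(self):
        model = load_clean("species:\nCdh1(p{low:high})\nglobals:\nlow = 0\nhigh = 10\n")
        assert list(model.state_list("Cdh1", "p").labels) == list(range(11))

    def test_enumeration_keeps_verbatim_order(self):
        site = parse_species("S(s2{2,4,6,8,0})").sites[0]
        assert list(resolve_state_list(site).labels) == [2, 4, 6, 8, 0]

    def test_inverted_range_is_empty(self):
        site = parse_species("S(p{5:3})").sites[0]
        assert len(resolve_state_list(site)) == 0

    def test_non_integer_bounds_floor(self):
        model = load_clean("species:\nS(p{0:hi})\nglobals:\nhi = 3.9\n")
        assert list(model.state_list("S", "p").labels) == [0, 1, 2, 3]


class TestSuccPred:
    NONCONSEC = StateList((2, 4, 6, 8, 0))
    SYMBOLIC = StateList(("free", "bound", "hidden"))
    CHAIN = StateList(tuple(range(11)))
    CIRC = StateList(tuple(range(11)), circular=True)

    def test_succ_follows_declaration_order_not_value(self):
        assert successor(self.NONCONSEC, 2) == 4
        assert successor(self.NONCONSEC, 8) == 0

    def test_succ_on_symbolic_states(self):
        assert successor(self.SYMBOLIC, "free") == "bound"

    def test_circular_wraps(self):
        assert successor(self.CIRC, 10) == 0
        assert predecessor(self.CIRC, 0) == 10

    def test_boundaries_error_when_not_circular(self):
        with pytest.raises(StateOrderError, match="successor of state 10 is not defined"):
            successor(self.CHAIN, 10)
        with pytest.raises(StateOrderError, match="predecessor of state 0"):
            predecessor(self.CHAIN, 0)

    def test_pred_mirrors_succ(self):
        assert predecessor(self.CHAIN, 1) == 0

    @given(
        labels=st.lists(st.integers(-50, 50), min_size=2, max_size=8, unique=True),
        circular=st.booleans(),
    )
    @settings(max_examples=200, derandomize=True)
    def test_pred_of_succ_is_identity_off_the_boundary(self, labels, circular):
        states = StateList(tuple(labels), circular=circular)
        for s in labels[:-1]:
            assert predecessor(states, successor(states, s)) == s

    @given(labels=st.lists(st.integers(-50, 50), min_size=1, max_size=8, unique=True))
    @settings(max_examples=200, derandomize=True)
    def test_circular_succ_composed_length_times_is_identity(self, labels):
        states = StateList(tuple(labels), circular=True)
        for s in labels:
            x = s
            for _ in range(len(labels)):
                x = successor(states, x)
            assert x == s


class TestEnumerateInstances:
    def test_eleven_forms(self, cdh1_model):
        instances = enumerate_instances(cdh1_model.species["Cdh1"], cdh1_model.globals)
        assert len(instances) == 11
        assert instances[0].name == "Cdh1_p0" and instances[-1].name == "Cdh1_p10"

    def test_two_sites_last_varies_fastest(self):
        model = load_clean("species:\nX(a{0:1}, b{free,bound}) = 1\n")
        names = [i.name for i in enumerate_instances(model.species["X"], model.globals)]
        assert names == ["X_a0_bfree", "X_a0_bbound", "X_a1_bfree", "X_a1_bbound"]

    def test_zero_site_species_single_instance_keeps_name(self, cdh1_model):
        instances = enumerate_instances(cdh1_model.species["ClbM"], cdh1_model.globals)
        assert [i.name for i in instances] == ["ClbM"]

    def test_per_state_initials_override_default(self):
        doc = "species:\nCdh1(p{0:2}) = 1\ninitials:\nCdh1(p{0}) = 5\n"
        model = load_clean(doc)
        amounts = {
            i.name: i.initial
            for i in enumerate_instances(model.species["Cdh1"], model.globals)
        }
        assert amounts == {"Cdh1_p0": 5.0, "Cdh1_p1": 1.0, "Cdh1_p2": 1.0}


class TestExpandReaction:
    def test_phosphorylation_chain_expands_to_ten(self, cdh1_model):
        flat = expand_reaction(cdh1_model.reactions[0], cdh1_model)
        assert len(flat) == 10
        moves = [(fr.reactants[0], fr.products[0]) for fr in flat]
        assert moves == [(f"Cdh1_p{i}", f"Cdh1_p{i + 1}") for i in range(10)]

    def test_translation_window_reaction_d2(self):
        model = fixtures.translation_toy(length=20, d=2)
        flat = expand_reaction(model.reactions[0], model)
        assert len(flat) == 2
        first = flat[0]
        assert first.reactants == ["R_c1"]
        assert first.products == ["P1_c2", "P2"]
        assert first.modifiers == ["M_c1"]

    def test_transfer_without_operator_copies_state(self):
        doc = (
            "species:\naatRNA_eEF1A_GTP = 1\n80S(codon{1:3}) = 1\n"
            "80S_aatRNA_eEF1A_GTP(codon{1:3}) = 0\n"
            "reactions:\naatRNA_eEF1A_GTP + 80S(codon) -> "
            "80S_aatRNA_eEF1A_GTP(codon=80S.codon) : MA(k)\nglobals:\nk = 1\n"
        )
        model = load_clean(doc)
        flat = expand_reaction(model.reactions[0], model)
        assert [(fr.reactants[1], fr.products[0]) for fr in flat] == [
            (f"80S_codon{i}", f"80S_aatRNA_eEF1A_GTP_codon{i}") for i in (1, 2, 3)
        ]

    def test_catalyst_with_sites_carries_state_through(self):
        doc = (
            "species:\nS(p{0:2}) = 1\nE(q{0:1}) = 1\n"
            "reactions:\nS(p{0:1}) + E -> S(succ(p)) + E : MA(k)\nglobals:\nk = 1\n"
        )
        model = load_clean(doc)
        flat = expand_reaction(model.reactions[0], model)
        # E iterates over its full list and its state carries through unchanged
        assert len(flat) == 4
        assert all(fr.reactants[1] == fr.products[1] for fr in flat)

    def test_count_law_product_of_admitted_states(self):
        doc = (
            "species:\nX(a{0:3}, b{0:4}) = 1\nY(c{0:2}) = 1\n"
            "reactions:\nX(a{1:2}) + Y -> X(succ(a)) + Y : MA(k)\nglobals:\nk = 1\n"
        )
        model = load_clean(doc)
        flat = expand_reaction(model.reactions[0], model)
        # a: 2 admitted, b: 5 (unconstrained), c: 3 (unconstrained) -> 30
        assert len(flat) == 2 * 5 * 3


class TestExpandSum:
    def test_restricted_sum_has_ten_terms(self, cdh1_model):
        node = parse_expression("SUM(Cdh1;p{1:10})")
        grounded = expand_sum(node, cdh1_model)
        text = unparse_expr(grounded)
        assert text == "+".join(f"Cdh1_p{i}" for i in range(1, 11))

    def test_unrestricted_sum_covers_all_states(self, cdh1_model):
        grounded = expand_sum(parse_expression("SUM(Cdh1)"), cdh1_model)
        assert unparse_expr(grounded).count("+") == 10  # 11 terms

    def test_moving_window_with_instance_environment(self, translation_model):
        node = parse_expression("SUM(R;c{M.c+1:M.c+14})")
        grounded = expand_sum(node, translation_model, env={("M", "c"): 1}, clip=True)
        assert unparse_expr(grounded) == "+".join(f"R_c{i}" for i in range(2, 16))

    def test_window_clipped_at_chain_end(self):
        model = fixtures.translation_toy(length=10, d=8)
        node = parse_expression("SUM(R;c{M.c+1:M.c+14})")
        grounded = expand_sum(node, model, env={("M", "c"): 8}, clip=True)
        assert unparse_expr(grounded) == "R_c9+R_c10"

    def test_out_of_range_restriction_errors_without_clip(self, cdh1_model):
        with pytest.raises(ExpansionError):
            expand_sum(parse_expression("SUM(Cdh1;p{1:12})"), cdh1_model)

    def test_weight_substitutes_site_value_per_term(self, cdh1_model):
        node = parse_expression("SUM(Cdh1;p{1:2};Cdh1.p)")
        grounded = expand_sum(node, cdh1_model)
        assert unparse_expr(grounded) == "1*Cdh1_p1+2*Cdh1_p2"


class TestRateLaws:
    def test_mass_action_multiplies_instances(self, cdh1_model):
        flat = expand_reaction(cdh1_model.reactions[0], cdh1_model)
        assert unparse_expr(flat[0].kinetic) == "kphos*Cdh1_p0*ClbM"

    def test_disordered_coefficient_is_N_minus_i(self):
        model = fixtures.xp_phosphorylation(N=5, mechanism="disordered")
        flat = expand_reaction(model.reactions[0], model)
        for i, fr in enumerate(flat):
            expected = BinOp(
                "*",
                BinOp(
                    "*",
                    BinOp("*", BinOp("-", Name("N"), Num(i)), Name("k")),
                    Name(f"XP_i{i}"),
                ),
                Name("Kin"),
            )
            assert fr.kinetic == expected

    def test_site_argument_on_symbolic_state_is_error(self):
        doc = (
            "species:\nS(s{free,bound}) = 1\nK = 1\n"
            "reactions:\nS(s{free}) + K -> S(succ(s)) + K : UD(f(S.s,S,K))\n"
            "functions:\nf(SITE i, SUB X, SUB E) = i*X*E\n"
        )
        model = load_clean(doc)
        with pytest.raises(ExpansionError, match="not an integer"):
            expand_reaction(model.reactions[0], model)


class TestExpandModel:
    def test_figure_counts(self, cdh1_model):
        flat = expand_model(cdh1_model)
        assert len(flat.species) == 12  # 11 Cdh1 forms + ClbM
        assert len(flat.reactions) == 20

    def test_refuses_on_error_issues(self):
        doc = "species:\na := k1*2\n"
        model, _ = load_model(doc, autocompletion_policy="off")
        with pytest.raises(ExpansionError) as exc:
            expand_model(model)
        assert exc.value.issues  # refusal lists the outstanding errors

    def test_single_global_change_rescales_network(self, cdh1_model):
        cdh1_model.globals["maxP"].initial_expr = Num(4)
        flat = expand_model(cdh1_model)
        assert len([s for s in flat.species if s.base == "Cdh1"]) == 5
        assert len(flat.reactions) == 8

    def test_empty_admitted_range_warns_and_expands_to_nothing(self):
        doc = (
            "species:\nS(p{0:5}) = 1\n"
            "reactions:\nS(p{4:2}) -> S(p{0}) : MA(k)\nglobals:\nk = 1\n"
        )
        model = load_clean(doc)
        flat = expand_model(model)
        assert flat.reactions == []
        assert any(i.code == "empty-range" for i in flat.issues)

    def test_deterministic_output(self, translation_model):
        from multistate.tables import flat_to_msl

        a = flat_to_msl(expand_model(translation_model))
        b = flat_to_msl(expand_model(fixtures.translation_toy()))
        assert a == b


# ---------------------------------------------------------------------------
# brute-force oracle equivalence on random small models
# ---------------------------------------------------------------------------

def _random_model_text(rng: random.Random):
    """One species S (1-3 sites, 2-5 consecutive integer states each), a
    zero-site catalyst E, and one reaction with random patterns."""
    n_sites = rng.randint(1, 3)
    sizes = [rng.randint(2, 5) for _ in range(n_sites)]
    sites = [chr(ord("a") + i) for i in range(n_sites)]
    site_defs = ", ".join(f"{s}{{0:{n - 1}}}" for s, n in zip(sites, sizes))

    admitted = {}
    reactant_pats = []
    product_pats = []
    for s, n in zip(sites, sizes):
        kind = rng.choice(["full", "omit", "fixed", "range"])
        if kind in ("full", "omit"):
            lo, hi = 0, n - 1
            if kind == "full":
                reactant_pats.append(s)
        elif kind == "fixed":
            lo = hi = rng.randrange(n)
            reactant_pats.append(f"{s}{{{lo}}}")
        else:
            lo = rng.randrange(n)
            hi = rng.randrange(lo, n)
            reactant_pats.append(f"{s}{{{lo}:{hi}}}")
        admitted[s] = (lo, hi)

        out = rng.choice(["carry", "succ", "pred", "fixed"])
        if out == "succ" and admitted[s][1] == n - 1:
            lo, hi = admitted[s]
            hi = n - 2
            if lo > hi or hi < 0:
                out = "carry"
            else:
                admitted[s] = (lo, hi)
                _set_pattern(reactant_pats, s, lo, hi)
        if out == "pred" and admitted[s][0] == 0:
            lo, hi = admitted[s]
            lo = 1
            if lo > hi:
                out = "carry"
            else:
                admitted[s] = (lo, hi)
                _set_pattern(reactant_pats, s, lo, hi)
        if out == "succ":
            product_pats.append(f"succ({s})")
        elif out == "pred":
            product_pats.append(f"pred({s})")
        elif out == "fixed":
            product_pats.append(f"{s}{{{rng.randrange(n)}}}")
        admitted[s] = admitted[s] + (out,)

    rpat = ", ".join(p for p in reactant_pats)
    ppat = ", ".join(product_pats)
    reaction = f"S({rpat})" if rpat else "S"
    product = f"S({ppat})" if ppat else "S"
    text = (
        f"species:\nS({site_defs}) = 1\nE = 1\n"
        f"reactions:\n{reaction} + E -> {product} + E : MA(k)\n"
        f"globals:\nk = 1\n"
    )
    return text, sites, sizes, admitted


def _set_pattern(pats, site, lo, hi):
    entry = f"{site}{{{lo}:{hi}}}"
    for i, p in enumerate(pats):
        if p == site or p.startswith(f"{site}{{"):
            pats[i] = entry
            return
    pats.append(entry)


def _brute_force(sites, sizes, admitted):
    """Try every full state combination; keep those the patterns admit;
    compute products by integer arithmetic."""
    out = []
    for combo in itertools.product(*(range(n) for n in sizes)):
        states = dict(zip(sites, combo))
        if any(not (admitted[s][0] <= states[s] <= admitted[s][1]) for s in sites):
            continue
        prod = {}
        for s in sites:
            op = admitted[s][2]
            if op == "carry":
                prod[s] = states[s]
            elif op == "succ":
                prod[s] = states[s] + 1
            elif op == "pred":
                prod[s] = states[s] - 1
            else:  # fixed label recorded separately below
                prod[s] = None
        out.append((states, prod))
    return out


def test_expander_matches_brute_force_on_random_models():
    rng = random.Random(20260930)
    checked = 0
    for _ in range(120):
        text, sites, sizes, admitted = _random_model_text(rng)
        model, issues = load_model(text, autocompletion_policy="off")
        assert errors(issues) == [], (text, [str(i) for i in issues])
        assert errors(validate(model)) == [], text
        flat = expand_reaction(model.reactions[0], model)
        got = sorted(
            (tuple(fr.reactants), tuple(fr.products)) for fr in flat
        )

        # independent enumeration
        ref = model.reactions[0]
        fixed_products = {}
        for site_name, pat in ref.products[0].site_patterns:
            from multistate._ast import FixedState

            if isinstance(pat, FixedState):
                fixed_products[site_name] = int(pat.value.value)
        expected = []
        for states, prod in _brute_force(sites, sizes, admitted):
            rname = "S" + "".join(f"_{s}{states[s]}" for s in sites)
            pvals = {s: fixed_products.get(s, prod[s]) for s in sites}
            pname = "S" + "".join(f"_{s}{pvals[s]}" for s in sites)
            expected.append(((rname, "E"), (pname, "E")))
        assert got == sorted(expected), text
        checked += 1
    assert checked >= 100
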