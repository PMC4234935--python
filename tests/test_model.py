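"""Semantic model: build policies, validation checks, refactoring, complexes."""
import pytest

from multistate import fixtures
from multistate._ast import Num
from multistate.issues import Severity, errors
from multistate.model import (
    Preferences,
    build_complex,
    confirm_pending,
    delete_entity,
    load_model,
    rename_entity,
    validate,
)
from multistate.parser import parse_expression
from multistate.states import StaticEvalError, evaluate_static


def load_clean(doc, policy="off"):
    model, issues = load_model(doc, autocompletion_policy=policy)
    assert errors(issues) == [], [str(i) for i in issues]
    return model


class TestAutocompletion:
    DOC = "reactions:\n-> A : MA(k)\nglobals:\nk = 1\n"

    def test_silent_creates_species_with_warning(self):
        model, issues = load_model(self.DOC, autocompletion_policy="silent")
        assert "A" in model.species
        assert model.species["A"].auto_created
        assert any(i.code == "auto-created" and i.severity is Severity.WARNING for i in issues)

    def test_off_leaves_undefined_with_error(self):
        model, issues = load_model(self.DOC, autocompletion_policy="off")
        assert "A" not in model.species
        assert any(i.code == "undef-species" and i.severity is Severity.ERROR for i in issues)

    def test_confirm_records_pending(self):
        model, issues = load_model(self.DOC, autocompletion_policy="confirm")
        assert model.pending_species == ["A"]
        assert "A" not in model.species
        confirm_pending(model)
        assert "A" in model.species and model.pending_species == []

    def test_fully_defined_model_has_zero_issues(self):
        model, issues = load_model(fixtures.cdh1_toy_msl(), autocompletion_policy="off")
        assert issues == [] and validate(model) == []

    def test_default_initial_from_preferences(self):
        prefs = Preferences(default_initial=7.5)
        model, _ = load_model(self.DOC, autocompletion_policy="silent", preferences=prefs)
        assert model.species["A"].default_initial == Num(7.5)


class TestEvaluateStatic:
    def test_fixed_global_arithmetic(self):
        model = load_clean("globals:\nhigh = 10\n")
        assert evaluate_static(parse_expression("high-1"), model.globals) == 9

    def test_non_integer_rounds_down(self):
        assert evaluate_static(parse_expression("7.8")) == 7
        model = load_clean("globals:\nx = 2.5\n")
        assert evaluate_static(parse_expression("x*3"), model.globals) == 7

    def test_species_reference_is_not_static(self):
        model = load_clean("species:\nA = 1\n")
        with pytest.raises(StaticEvalError):
            evaluate_static(parse_expression("A+1"), model.globals)

    def test_assigned_global_is_not_static(self):
        model = load_clean("species:\nA = 1\nglobals:\ntot := A*2\n")
        with pytest.raises(StaticEvalError):
            evaluate_static(parse_expression("tot"), model.globals)


class TestValidate:
    def test_succ_of_last_state_is_range_coherence_error(self):
        doc = (
            "species:\nCdh1(p{0:10})\nClbM\n"
            "reactions:\nCdh1(p{0:10}) + ClbM -> Cdh1(succ(p)) + ClbM : MA(k)\n"
            "globals:\nk = 1\n"
        )
        model, _ = load_model(doc, autocompletion_policy="off")
        issues = validate(model)
        coherence = [i for i in issues if i.code == "range-coherence"]
        assert len(coherence) == 1
        assert "the successor of state 10 is not defined" in coherence[0].message

    def test_undefined_identifiers_in_expressions(self):
        # two species whose expressions involve k1 and c, neither defined
        doc = "species:\na := k1*2\nb := c+1\n"
        model, issues = load_model(doc, autocompletion_policy="off")
        all_issues = issues + validate(model)
        undef = {i.message.split("'")[1] for i in all_issues if i.code == "undef-identifier"}
        assert undef == {"k1", "c"}
        assert all(i.severity is Severity.ERROR for i in all_issues)

    def test_sum_restriction_with_variable_bounds_ok(self):
        doc = (
            "species:\nCdh1(p{0:10}) = 1\n"
            "globals:\nlow = 1\nmiddle = 5\ntot := SUM(Cdh1;p{low:middle})\n"
        )
        model = load_clean(doc)
        assert validate(model) == []

    def test_sum_restriction_outside_state_list(self):
        doc = "species:\nCdh1(p{0:10}) = 1\nglobals:\ntot := SUM(Cdh1;p{1:12})\n"
        model, _ = load_model(doc, autocompletion_policy="off")
        assert any(i.code == "sum-out-of-range" for i in validate(model))

    def test_non_static_range_bound(self):
        doc = "species:\nA = 1\nCdh1(p{0:A})\n"
        model, _ = load_model(doc, autocompletion_policy="off")
        assert any(i.code == "non-static-range" for i in validate(model))

    def test_function_arity_mismatch(self):
        doc = (
            "species:\nXP(i{0:4}) = 1\nKin = 1\n"
            "reactions:\nXP(i{0:3}) + Kin -> XP(succ(i)) + Kin : UD(dis(XP.i,k))\n"
            "globals:\nk = 1\n"
            "functions:\ndis(GLQ N, SITE i, GLQ k, SUB X, SUB K) = (N-i)*k*X*K\n"
        )
        model, _ = load_model(doc, autocompletion_policy="off")
        assert any(i.code == "func-arity" for i in validate(model))

    def test_site_parameter_requires_accessor(self):
        doc = (
            "species:\nXP(i{0:4}) = 1\nKin = 1\n"
            "reactions:\nXP(i{0:3}) + Kin -> XP(succ(i)) + Kin : UD(dis(N,k,k,XP,Kin))\n"
            "globals:\nk = 1\nN = 5\n"
            "functions:\ndis(GLQ N, SITE i, GLQ k, SUB X, SUB K) = (N-i)*k*X*K\n"
        )
        model, _ = load_model(doc, autocompletion_policy="off")
        assert any(i.code == "func-role" for i in validate(model))

    def test_transfer_incompatible_states(self):
        # source site ranges over 1..5 but target only accepts 1..3
        doc = (
            "species:\nA(c{1:5}) = 1\nB(c{1:3}) = 0\n"
            "reactions:\nA(c) -> B(c=A.c) : MA(k)\n"
            "globals:\nk = 1\n"
        )
        model, _ = load_model(doc, autocompletion_policy="off")
        assert any(i.code == "transfer-incompatible" for i in validate(model))

    def test_validate_is_pure(self, cdh1_model):
        assert validate(cdh1_model) == validate(cdh1_model)

    def test_model_with_errors_serializes_and_reparses_losslessly(self):
        doc = "species:\na := k1*2\n"
        model, _ = load_model(doc, autocompletion_policy="off")
        assert errors(validate(model))  # it does carry an error
        text = model.to_msl()
        model2, _ = load_model(text, autocompletion_policy="off")
        assert model2.to_msl() == text


class TestRename:
    def test_species_rename_propagates_everywhere(self, cdh1_model):
        renamed = rename_entity(cdh1_model, "Cdh1", "CDH1")
        text = renamed.to_msl()
        assert "Cdh1T" in text  # the distinct aggregate name is untouched
        assert "Cdh1(" not in text and "SUM(Cdh1;" not in text
        assert "CDH1(" in text and "SUM(CDH1;" in text
        assert validate(renamed) == []

    def test_site_rename_propagates_to_reactions_and_sums(self, cdh1_model):
        renamed = rename_entity(cdh1_model, "Cdh1.p", "q")
        text = renamed.to_msl()
        assert "p{" not in text and "succ(q)" in text and "SUM(Cdh1;q{" in text
        assert validate(renamed) == []

    def test_rename_then_reverse_is_identity(self, cdh1_model):
        back = rename_entity(rename_entity(cdh1_model, "Cdh1", "X9"), "X9", "Cdh1")
        assert back.to_msl() == cdh1_model.to_msl()

    def test_rename_to_same_name_is_identity(self, cdh1_model):
        assert rename_entity(cdh1_model, "Cdh1", "Cdh1").to_msl() == cdh1_model.to_msl()

    def test_collision_rejected_model_unchanged(self, cdh1_model):
        before = cdh1_model.to_msl()
        with pytest.raises(ValueError):
            rename_entity(cdh1_model, "Cdh1", "ClbM")
        assert cdh1_model.to_msl() == before


class TestDelete:
    SCENARIO = (
        "species:\na = 1\nb = 0\nd := 2*a\n"
        "reactions:\na -> b : MA(k1)\n"
        "globals:\nk1 = 0.1*a\n"
    )

    def test_three_outcomes_per_reference(self):
        model = load_clean(self.SCENARIO)
        out, issues = delete_entity(
            model,
            "a",
            overrides={
                ("reaction", 0): "cascade",
                ("species", "d"): "leave_dangling",
                ("global", "k1"): ("replace_with", 5),
            },
        )
        assert "a" not in out.species
        assert out.reactions == []  # cascaded
        text = out.to_msl()
        assert "d := 2*a" in text  # inconsistency left in place
        assert "k1 = 0.1*5" in text  # numeric replacement
        assert [i.code for i in issues] == ["dangling-reference"]
        # a model saved with errors re-parses losslessly
        model2, _ = load_model(text, autocompletion_policy="off")
        assert model2.to_msl() == text

    def test_cascade_leaves_no_dangling_references(self):
        model = load_clean(self.SCENARIO)
        out, issues = delete_entity(model, "a", policy="cascade")
        assert issues == []
        remaining = validate(out)
        assert not any("'a'" in i.message for i in remaining)

    def test_delete_unreferenced_entity_is_clean(self):
        model = load_clean("species:\nA = 1\nB = 2\n")
        out, issues = delete_entity(model, "B")
        assert "B" not in out.species and issues == []

    def test_replace_with_on_participant_rejected(self):
        model = load_clean(self.SCENARIO)
        out, issues = delete_entity(model, "a", policy=("replace_with", 3))
        assert any(i.code == "replace-in-reaction" for i in issues)
        assert len(out.reactions) == 1  # reaction kept, reference dangling


class TestComplexes:
    def test_restricted_complex_site(self):
        doc = "species:\nNet1(p{0:8}) = 1\nCdc14 = 1\n"
        model = load_clean(doc)
        cx, rxns = build_complex(
            model, [("Net1", [("p", (0, 5))]), ("Cdc14", [])], generate_reactions=True
        )
        assert cx.name == "Net1_Cdc14"  # auto-named from components
        site = model.species["Net1_Cdc14"].sites[0]
        assert site.name == "p"
        states = model.state_list("Net1_Cdc14", "p")
        assert list(states.labels) == [0, 1, 2, 3, 4, 5]
        assert len(rxns) == 2
        assert validate(model) == []

    def test_generated_reactions_transfer_state(self):
        doc = "species:\nNet1(p{0:8}) = 1\nCdc14 = 1\n"
        model = load_clean(doc)
        build_complex(
            model, [("Net1", [("p", (0, 5))]), ("Cdc14", [])], generate_reactions=True
        )
        from multistate.expand import expand_model

        flat = expand_model(model)
        # 9 Net1 + 1 Cdc14 + 6 complex forms
        assert len(flat.species) == 16
        # 6 complexation + 6 decomplexation
        assert len(flat.reactions) == 12

    def test_zero_site_complex_is_plain_species_with_two_reactions(self):
        model = load_clean("species:\nA = 1\nB = 1\n")
        cx, rxns = build_complex(model, [("A", []), ("B", [])], generate_reactions=True)
        assert model.species["A_B"].sites == []
        assert len(rxns) == 2
        assert validate(model) == []

    def test_restriction_outside_state_list_rejected(self):
        model = load_clean("species:\nNet1(p{0:8}) = 1\nCdc14 = 1\n")
        with pytest.raises(ValueError):
            build_complex(model, [("Net1", [("p", (0, 9))]), ("Cdc14", [])])

    def test_auto_name_follows_component_rename(self):
        model = load_clean("species:\nNet1(p{0:8}) = 1\nCdc14 = 1\n")
        build_complex(model, [("Net1", [("p", (0, 5))]), ("Cdc14", [])])
        renamed = rename_entity(model, "Net1", "NET1")
        assert "NET1_Cdc14" in renamed.complexes
        assert "Net1_Cdc14" not in renamed.complexes

    def test_complex_round_trips_through_msl(self):
        model = load_clean("species:\nNet1(p{0:8}) = 1\nCdc14 = 1\n")
        build_complex(
            model, [("Net1", [("p", (0, 5))]), ("Cdc14", [])], generate_reactions=True
        )
        text = model.to_msl()
        assert "complexes:" in text
        model2, issues = load_model(text, autocompletion_policy="off")
        assert errors(issues) == []
        assert model2.to_msl() == text


class TestPreferences:
    def test_from_file(self, tmp_path):
        p = tmp_path / "prefs.cfg"
        p.write_text(
            "# prefs\nautocompletion_policy = off\ndefault_initial = 3.5\n"
            "default_delete_policy = leave_dangling\n"
        )
        prefs = Preferences.from_file(p)
        assert prefs.autocompletion_policy == "off"
        assert prefs.default_initial == 3.5
        assert prefs.default_delete_policy == "leave_dangling"
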