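"""SBML/CSV export, model statistics, and the command-line interface."""
import json
import xml.etree.ElementTree as ET

import pandas as pd
import pytest
from click.testing import CliRunner

from multistate import fixtures
from multistate.cli import main
from multistate.expand import FlatModel, expand_model
from multistate.sbml import MATHML_NS, SBML_NS, check_sbml, sanitize_id, write_sbml
from multistate.tables import (
    flat_to_msl,
    model_stats,
    parameters_frame,
    read_tables,
    reactions_frame,
    species_frame,
    write_tables,
)


class TestSBML:
    def test_cdh1_document_counts(self, cdh1_model):
        doc = write_sbml(expand_model(cdh1_model))
        root = ET.fromstring(doc)
        species = root.findall(f".//{{{SBML_NS}}}species")
        reactions = root.findall(f".//{{{SBML_NS}}}reaction")
        assert len(species) == 12 and len(reactions) == 20
        assert check_sbml(doc) == []

    @pytest.mark.parametrize("name", sorted(fixtures.FIXTURES))
    def test_every_fixture_passes_consistency_check(self, name):
        flat = expand_model(fixtures.FIXTURES[name].builder())
        assert check_sbml(write_sbml(flat)) == []

    def test_illegal_leading_digit_id_sanitized_name_preserved(self):
        from multistate.model import load_model

        doc = (
            "species:\n80S(codon{1:2}) = 1\nX = 1\n"
            "reactions:\n80S(codon{1:1}) + X -> 80S(succ(codon)) + X : MA(k)\n"
            "globals:\nk = 1\n"
        )
        model, _ = load_model(doc, autocompletion_policy="off")
        sbml = write_sbml(expand_model(model))
        root = ET.fromstring(sbml)
        ids = {s.get("id"): s.get("name") for s in root.findall(f".//{{{SBML_NS}}}species")}
        assert "_80S_codon1" in ids and ids["_80S_codon1"] == "80S_codon1"
        assert check_sbml(sbml) == []

    def test_sanitize_collision_gets_deterministic_suffix(self):
        taken = {}
        a = sanitize_id("80S", taken)
        taken["80S"] = a
        b = sanitize_id("_80S", taken)
        assert a == "_80S" and b == "_80S_2"

    def test_empty_model_is_minimal_valid_document(self):
        doc = write_sbml(FlatModel())
        assert check_sbml(doc) == []
        root = ET.fromstring(doc)
        assert root.get("level") == "3" and root.get("version") == "1"

    def test_assignment_rules_emitted_with_math(self, translation_model):
        doc = write_sbml(expand_model(translation_model))
        root = ET.fromstring(doc)
        rules = root.findall(f".//{{{SBML_NS}}}assignmentRule")
        assert len(rules) == 3  # one moving-window rule per modifier instance
        for rule in rules:
            assert rule.find(f"{{{MATHML_NS}}}math") is not None
        assert check_sbml(doc) == []

    def test_byte_identical_across_runs(self, cdh1_model):
        a = write_sbml(expand_model(cdh1_model))
        b = write_sbml(expand_model(fixtures.cdh1_toy()))
        assert a == b

    def test_checker_catches_broken_documents(self, cdh1_model):
        doc = write_sbml(expand_model(cdh1_model))
        broken = doc.replace('species="Cdh1_p0"', 'species="NoSuch"', 1)
        assert any("NoSuch" in p for p in check_sbml(broken))


class TestTables:
    def test_cdh1_reaction_table_has_twenty_rows(self, cdh1_model):
        frame = reactions_frame(expand_model(cdh1_model))
        assert len(frame) == 20
        assert frame.loc[0, "reaction"] == "Cdh1_p0 + ClbM -> Cdh1_p1 + ClbM"
        assert frame.loc[0, "kinetic_law"] == "kphos*Cdh1_p0*ClbM"

    def test_empty_model_gives_header_only_files(self, tmp_path):
        paths = write_tables(FlatModel(), tmp_path)
        for path in paths.values():
            frame = pd.read_csv(path)
            assert len(frame) == 0

    def test_round_trip_equals_written_frames(self, cdh1_model, tmp_path):
        flat = expand_model(cdh1_model)
        write_tables(flat, tmp_path)
        back = read_tables(tmp_path)
        pd.testing.assert_frame_equal(back["species"], species_frame(flat))
        pd.testing.assert_frame_equal(back["reactions"], reactions_frame(flat))
        got = back["parameters"].astype(str)
        want = parameters_frame(flat).astype(str)
        pd.testing.assert_frame_equal(got, want)


class TestStats:
    def test_cdh1_reduction(self, cdh1_model):
        stats = model_stats(cdh1_model, expand_model(cdh1_model))
        assert (stats.compact_reactions, stats.flat_reactions) == (2, 20)
        assert stats.reaction_reduction == pytest.approx(0.90)
        assert 0 <= stats.species_reduction <= 1

    def test_zero_multistate_model_has_zero_reduction(self):
        from multistate.model import load_model

        doc = "species:\nA = 1\nB = 0\nreactions:\nA -> B : MA(k)\nglobals:\nk = 1\n"
        model, _ = load_model(doc, autocompletion_policy="off")
        stats = model_stats(model, expand_model(model))
        assert stats.species_reduction == 0.0 and stats.reaction_reduction == 0.0

    def test_xp_compact_one_to_flat_five(self):
        model = fixtures.xp_phosphorylation(N=5)
        stats = model_stats(model, expand_model(model))
        assert (stats.compact_reactions, stats.flat_reactions) == (1, 5)


class TestCLI:
    def _write(self, tmp_path, text):
        path = tmp_path / "model.msl"
        path.write_text(text, encoding="utf-8")
        return str(path)

    def test_expand_then_stats_report_figure_counts(self, tmp_path):
        runner = CliRunner()
        path = self._write(tmp_path, fixtures.cdh1_toy_msl())
        out = tmp_path / "flat.msl"
        result = runner.invoke(main, ["expand", path, "--out", str(out)])
        assert result.exit_code == 0
        assert len([l for l in out.read_text().splitlines() if "->" in l]) == 20
        result = runner.invoke(main, ["stats", path])
        assert result.exit_code == 0
        stats = json.loads(result.output)
        assert stats["compact_reactions"] == 2 and stats["flat_reactions"] == 20

    def test_flat_msl_output_reparses_cleanly(self, tmp_path):
        from multistate.model import load_model

        runner = CliRunner()
        path = self._write(tmp_path, fixtures.cdh1_toy_msl())
        result = runner.invoke(main, ["expand", path])
        assert result.exit_code == 0
        model, issues = load_model(result.output, autocompletion_policy="off")
        from multistate.issues import errors

        assert errors(issues) == []
        assert len(model.reactions) == 20

    def test_validate_reports_undefined_names_nonzero_exit(self, tmp_path):
        runner = CliRunner()
        path = self._write(tmp_path, "species:\na := k1*2\nb := c+1\n")
        result = runner.invoke(main, ["validate", path])
        assert result.exit_code == 1
        diags = [json.loads(line) for line in result.output.splitlines()]
        assert len(diags) >= 2
        assert {"k1", "c"} <= {d["message"].split("'")[1] for d in diags}

    def test_validate_clean_model_exits_zero(self, tmp_path):
        runner = CliRunner()
        path = self._write(tmp_path, fixtures.cdh1_toy_msl())
        result = runner.invoke(main, ["validate", path])
        assert result.exit_code == 0

    def test_export_sbml_empty_model(self, tmp_path):
        runner = CliRunner()
        path = self._write(tmp_path, "")
        out = tmp_path / "empty.xml"
        result = runner.invoke(main, ["export", path, "--format", "sbml", "--out", str(out)])
        assert result.exit_code == 0
        assert check_sbml(out.read_text()) == []

    def test_export_csv_writes_three_tables(self, tmp_path):
        runner = CliRunner()
        path = self._write(tmp_path, fixtures.cdh1_toy_msl())
        outdir = tmp_path / "tables"
        result = runner.invoke(main, ["export", path, "--format", "csv", "--out", str(outdir)])
        assert result.exit_code == 0
        assert {p.name for p in outdir.iterdir()} == {
            "species.csv",
            "reactions.csv",
            "parameters.csv",
        }

    def test_unreadable_input_exits_two(self, tmp_path):
        runner = CliRunner()
        result = runner.invoke(main, ["validate", str(tmp_path / "missing.msl")])
        assert result.exit_code == 2


def test_flat_msl_round_trip_preserves_network(translation_model):
    from multistate.issues import errors
    from multistate.model import load_model

    flat = expand_model(translation_model)
    text = flat_to_msl(flat)
    model, issues = load_model(text, autocompletion_policy="off")
    assert errors(issues) == []
    flat2 = expand_model(model)
    assert [r.reaction_string() for r in flat2.reactions] == [
        r.reaction_string() for r in flat.reactions
    ]
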