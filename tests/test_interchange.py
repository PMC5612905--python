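"""SDF/XLSX round trips, enrichment contract, reaction reports."""

import json
from pathlib import Path

import pytest

from elnkit import interchange as ix, registry, stoichiometry as stoi
from elnkit.chemgraph import StructureKey, graph_from_smiles, parse_molfile
from elnkit.errors import ValidationError
from elnkit.store import Store

from helpers import graphs_isomorphic

FIXTURES = Path(__file__).parent / "data" / "enrichment"


def _populate(store, n=2):
    smiles = ["CCO", "CC(=O)O", "CCC", "c1ccccc1", "CCN"][:n]
    samples = []
    for s in smiles:
        m = registry.register_molecule(graph_from_smiles(s, s), store)
        samples.append(registry.create_sample(
            m, "PT", store, purity=0.95, description=f"batch of {s}"))
    return samples


class TestExportSdf:
    def test_record_and_item_counts(self, store):
        samples = _populate(store, 2)
        sel = ix.ExportSelection(("label", "average_mass"))
        sdf = ix.export_sdf(samples, sel, store)
        assert sdf.count("$$$$") == 2
        assert sdf.count("> <LABEL>") == 2
        assert sdf.count("> <AVERAGE_MASS>") == 2

    def test_deselected_field_absent(self, store):
        samples = _populate(store, 1)
        sdf = ix.export_sdf(samples, ix.ExportSelection(("label",)), store)
        assert "<CAS>" not in sdf

    def test_zero_samples_valid_empty_file(self, store):
        assert ix.export_sdf([], ix.ExportSelection(("label",)), store) == ""

    def test_empty_selection_rejected(self):
        with pytest.raises(ValidationError):
            ix.ExportSelection(())

    def test_unknown_field_rejected(self):
        with pytest.raises(ValidationError):
            ix.ExportSelection(("label", "favourite_colour"))


class TestImportSdf:
    def test_round_trip_preserves_structures_and_fields(self, store):
        samples = _populate(store, 3)
        sel = ix.ExportSelection(("label", "purity", "description",
                                  "average_mass", "formula"))
        sdf = ix.export_sdf(samples, sel, store)
        target = Store()
        report = ix.import_sdf(sdf, target)
        assert report.created_samples == 3 and not report.diagnostics
        for src, sid in zip(samples, report.sample_ids):
            dst = registry.get_sample(target, sid)
            assert graphs_isomorphic(parse_molfile(src.molfile),
                                     parse_molfile(dst.molfile))
            assert dst.purity == src.purity
            assert dst.description == src.description
            assert dst.external_label == src.rendered_label
            src_m = registry.get_molecule(store, src.molecule_id)
            dst_m = registry.get_molecule(target, dst.molecule_id)
            assert (dst_m.sum_formula, dst_m.average_mass) \
                == (src_m.sum_formula, src_m.average_mass)

    def test_identical_structures_merge_to_one_molecule(self, store):
        m = registry.register_molecule(graph_from_smiles("CCO"), store)
        s1 = registry.create_sample(m, "PT", store)
        s2 = registry.create_sample(m, "PT", store)
        sdf = ix.export_sdf([s1, s2], ix.ExportSelection(("label",)), store)
        target = Store()
        report = ix.import_sdf(sdf, target)
        assert report.created_molecules == 1
        assert report.merged_molecules == 1
        assert report.created_samples == 2

    def test_corrupt_record_skipped_with_diagnostic(self, store):
        samples = _populate(store, 3)
        sdf = ix.export_sdf(samples, ix.ExportSelection(("label",)), store)
        records = sdf.split("$$$$\n")
        records[1] = "garbage not a molfile\nM  END\n" + records[1].split(
            "M  END\n", 1)[-1]
        corrupted = "$$$$\n".join(records)
        target = Store()
        report = ix.import_sdf(corrupted, target)
        assert report.created_samples == 2
        assert report.skipped_records == 1
        assert len(report.diagnostics) == 1 and "record 2" in \
            report.diagnostics[0]

    def test_unknown_items_kept_as_extras(self, store):
        samples = _populate(store, 1)
        sdf = ix.export_sdf(samples, ix.ExportSelection(("label",)), store)
        sdf = sdf.replace("$$$$", "> <MYSTERY>\n42\n\n$$$$")
        report = ix.import_sdf(sdf, Store())
        assert report.extras[0] == {"MYSTERY": "42"}


class TestTable:
    def test_round_trip_field_equal(self, store, tmp_path):
        samples = _populate(store, 3)
        sel = ix.ExportSelection(("label", "molfile", "canonical_smiles",
                                  "purity", "description"))
        path = tmp_path / "samples.xlsx"
        ix.export_table(samples, sel, store, str(path))
        target = Store()
        report = ix.import_table(str(path), target)
        assert report.created_samples == 3 and not report.diagnostics
        for src, sid in zip(samples, report.sample_ids):
            dst = registry.get_sample(target, sid)
            assert dst.purity == src.purity
            assert dst.description == src.description
            assert graphs_isomorphic(parse_molfile(src.molfile),
                                     parse_molfile(dst.molfile))

    def test_header_follows_selection_order(self, store, tmp_path):
        from openpyxl import load_workbook
        samples = _populate(store, 1)
        sel = ix.ExportSelection(("purity", "label", "molfile"))
        path = tmp_path / "ordered.xlsx"
        ix.export_table(samples, sel, store, str(path))
        ws = load_workbook(str(path)).active
        assert [c.value for c in ws[1]] == ["purity", "label", "molfile"]

    def test_missing_structure_column_rejected(self, store, tmp_path):
        from openpyxl import Workbook
        wb = Workbook()
        wb.active.append(["label", "purity"])
        path = tmp_path / "nostructure.xlsx"
        wb.save(str(path))
        with pytest.raises(ValidationError, match="structure column"):
            ix.import_table(str(path), Store())


class TestEnrichmentContract:
    def test_query_targets_exact_structure_by_inchikey(self):
        key = StructureKey("inchikey", "LFQSCWFLJHTTHZ-UHFFFAOYSA-N")
        query = ix.build_enrichment_query(key)
        assert query["operation"] == "exact_structure"
        assert query["namespace"] == "inchikey"
        assert key.value in query["url"]

    def test_fallback_key_cannot_query_live(self):
        with pytest.raises(ValidationError):
            ix.build_enrichment_query(StructureKey("fallback", "ABC"))

    def test_ethanol_fixture_parses(self):
        record = ix.parse_enrichment_response(
            (FIXTURES / "ethanol.json").read_text())
        assert record.hit and record.cid == "702"
        assert record.iupac_name == "ethanol"
        assert len(record.cas_numbers) >= 1

    def test_nomatch_fixture_is_a_miss_not_an_error(self):
        record = ix.parse_enrichment_response(
            (FIXTURES / "nomatch.json").read_text())
        assert not record.hit and record.cid is None

    def test_malformed_payload_quoted_in_error(self):
        with pytest.raises(ValidationError, match="not json at all"):
            ix.parse_enrichment_response("not json at all")

    def test_presence_flag_shows_in_molecule_list(self, store):
        m = registry.register_molecule(graph_from_smiles("CCO", "ethanol"),
                                       store)
        record = ix.parse_enrichment_response(
            (FIXTURES / "ethanol.json").read_text())
        m = registry.enrich_molecule(m, record, store)
        registry.create_sample(m, "PT", store)
        summary = registry.list_samples(store)[0]
        assert summary["external_db"]["pubchem"] is True
        assert m.external_refs["pubchem"]["identifier"] == "702"

    def test_enrichment_never_mutates_structure_or_key(self, store):
        m = registry.register_molecule(graph_from_smiles("CCO"), store)
        record = ix.parse_enrichment_response(
            (FIXTURES / "ethanol.json").read_text())
        enriched = registry.enrich_molecule(m, record, store)
        assert enriched.key == m.key and enriched.molfile == m.molfile


class TestReactionReport:
    def _reaction(self, store):
        eth = registry.register_molecule(graph_from_smiles("CCO", "ethanol"),
                                         store)
        s_ref = registry.create_sample(eth, "PT", store)
        p1 = registry.create_sample(eth, "PT", store)
        p2 = registry.create_sample(eth, "PT", store)
        r = stoi.new_reaction("PT", store)
        stoi.add_participant(r, s_ref.id, "starting_material",
                             target=stoi.AmountTriple(1.0, "mmol"),
                             real=stoi.AmountTriple(1.0, "mmol"))
        stoi.add_participant(r, p1.id, "product",
                             real=stoi.AmountTriple(0.5, "mmol"))
        stoi.add_participant(r, p2.id, "product")
        registry.add_analysis(p1, "NMR", store, status="confirmed")
        stoi.save_reaction(r, store)
        return r

    def test_two_products_two_analysis_subsections(self, store):
        r = self._reaction(store)
        report = ix.reaction_report(r, store)
        assert report.count("### Product") == 2
        assert "- NMR: confirmed" in report

    def test_yield_line_only_when_computable(self, store):
        r = self._reaction(store)
        report = ix.reaction_report(r, store)
        lines = [ln for ln in report.splitlines() if "| product |" in ln]
        assert "50.0%" in lines[0]
        assert lines[1].rstrip().endswith("|  |")  # no real amount, no yield

    def test_report_is_deterministic(self, store):
        r = self._reaction(store)
        assert ix.reaction_report(r, store) == ix.reaction_report(r, store)
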