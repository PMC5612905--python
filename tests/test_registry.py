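"""Registration, deduplication, genealogy labels, CAS handling."""

import random

import pytest
from hypothesis import given, settings, strategies as st

from elnkit import registry
from elnkit.chemgraph import StructureKey
from elnkit.errors import IntegrityError, NotFoundError, ValidationError
from elnkit.fixtures import FixtureSpec, generate_fixtures
from elnkit.interchange import ExternalRecord
from elnkit.registry import (SampleLabel, assign_cas, cas_check_digit_ok,
                             create_sample, derive_child_sample,
                             enrich_molecule, list_samples, parse_label,
                             register_molecule)

from helpers import count_distinct_structures


class TestRegisterMolecule:
    def test_new_structure_creates_entry(self, store, ethanol):
        m = register_molecule(ethanol, store)
        assert m.sum_formula == "C2H6O"
        assert store.one("SELECT COUNT(*) AS n FROM molecules")["n"] == 1

    def test_reregistration_returns_same_molecule(self, store, ethanol):
        m1 = register_molecule(ethanol, store)
        m2 = register_molecule(ethanol, store)
        assert m1.id == m2.id
        assert store.one("SELECT COUNT(*) AS n FROM molecules")["n"] == 1

    def test_atom_permuted_copy_deduplicates(self, store, ethanol):
        m1 = register_molecule(ethanol, store)
        m2 = register_molecule(ethanol.permuted([2, 0, 1]), store)
        assert m1.id == m2.id

    def test_dedup_count_matches_isomorphism_oracle(self, store):
        graphs = generate_fixtures(FixtureSpec(seed=11, n_molecules=40))
        for g in graphs:
            register_molecule(g, store, backend="fallback")
        k = count_distinct_structures(graphs)
        assert store.one("SELECT COUNT(*) AS n FROM molecules")["n"] == k
        assert k < len(graphs)  # the duplicate rate produced real duplicates


class TestEnrichment:
    def _record(self, molecule, **kw):
        defaults = dict(source="pubchem", key=molecule.key, cid="702",
                        iupac_name="ethanol", canonical_smiles="CCO",
                        cas_numbers=("64-17-5", "8024-45-1"), hit=True,
                        query_date="2017-09-25")
        defaults.update(kw)
        return ExternalRecord(**defaults)

    def test_all_cas_candidates_are_stored(self, store, ethanol):
        m = register_molecule(ethanol, store)
        m = enrich_molecule(m, self._record(m), store)
        assert m.cas_numbers == ["64-17-5", "8024-45-1"]
        assert m.external_refs["pubchem"]["identifier"] == "702"

    def test_key_mismatch_is_an_integrity_error(self, store, ethanol):
        m = register_molecule(ethanol, store)
        bad = self._record(m, key=StructureKey("inchikey", "X" * 27))
        with pytest.raises(IntegrityError):
            enrich_molecule(m, bad, store)

    def test_reenrichment_is_idempotent(self, store, ethanol):
        m = register_molecule(ethanol, store)
        record = self._record(m)
        once = enrich_molecule(m, record, store)
        twice = enrich_molecule(once, record, store)
        assert once == twice

    def test_user_edited_name_is_never_overwritten(self, store, ethanol):
        m = register_molecule(ethanol, store)
        m = registry.set_molecule_name(m, "my special batch name", store)
        m = enrich_molecule(m, self._record(m), store)
        assert m.iupac_name == "my special batch name"


class TestSampleLifecycle:
    def test_per_user_sequence(self, store, ethanol, water):
        m1 = register_molecule(ethanol, store)
        m2 = register_molecule(water, store)
        create_sample(m1, "PT", store)
        create_sample(m2, "PT", store)
        third = create_sample(m1, "pt", store)  # initials case-folded
        other = create_sample(m1, "AB", store)
        assert third.rendered_label == "PT-3"
        assert other.rendered_label == "AB-1"

    def test_purity_validation(self, store, ethanol):
        m = register_molecule(ethanol, store)
        with pytest.raises(ValidationError):
            create_sample(m, "PT", store, purity=1.5)
        with pytest.raises(ValidationError):
            create_sample(m, "PT", store, purity=0.0)

    def test_sample_molfile_restyle_keeps_molecule_key(self, store, ethanol):
        from elnkit.chemgraph import write_molfile
        m = register_molecule(ethanol, store)
        s = create_sample(m, "PT", store)
        restyled = write_molfile(ethanol.permuted([2, 1, 0]))
        s = registry.update_sample(s, store, molfile=restyled)
        assert s.molfile == restyled

    def test_sample_molfile_cannot_change_structure(self, store, ethanol,
                                                    propanol):
        from elnkit.chemgraph import write_molfile
        m = register_molecule(ethanol, store)
        s = create_sample(m, "PT", store)
        with pytest.raises(IntegrityError):
            registry.update_sample(s, store, molfile=write_molfile(propanol))


class TestGenealogy:
    def test_children_extend_the_parent_label(self, store, ethanol):
        m = register_molecule(ethanol, store)
        for _ in range(3):
            create_sample(m, "PT", store)
        parent = registry.get_sample(store, 3)
        assert parent.rendered_label == "PT-3"
        c1 = derive_child_sample(parent, store)
        c2 = derive_child_sample(parent, store)
        grandchild = derive_child_sample(c1, store)
        assert c1.rendered_label == "PT-3-1"
        assert c2.rendered_label == "PT-3-2"
        assert grandchild.rendered_label == "PT-3-1-1"
        assert grandchild.parent_id == c1.id

    def test_child_inherits_molecule_purity_molfile(self, store, ethanol):
        m = register_molecule(ethanol, store)
        s = create_sample(m, "PT", store, purity=0.9)
        child = derive_child_sample(s, store)
        assert (child.molecule_id, child.purity, child.molfile) \
            == (s.molecule_id, s.purity, s.molfile)

    def test_labels_unique_across_store(self, store, ethanol):
        m = register_molecule(ethanol, store)
        labels = set()
        samples = [create_sample(m, "PT", store) for _ in range(5)]
        for s in samples[:3]:
            samples.append(derive_child_sample(s, store))
        for s in samples:
            labels.add(s.rendered_label)
        assert len(labels) == len(samples)


class TestLabelGrammar:
    @pytest.mark.parametrize("text, expected", [
        ("PT-3-2", SampleLabel("PT", 3, (2,))),
        ("AB-10", SampleLabel("AB", 10, ())),
        ("XYZ-1-2-3", SampleLabel("XYZ", 1, (2, 3))),
    ])
    def test_parse_examples(self, text, expected):
        assert parse_label(text) == expected

    @pytest.mark.parametrize("bad", ["pt3", "PT", "PT-0", "PT-1-0", "pt-1",
                                     "PT-1-", "1-PT", ""])
    def test_malformed_labels_rejected(self, bad):
        with pytest.raises(ValidationError):
            parse_label(bad)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(initials=st.text(alphabet=st.characters(min_codepoint=65,
                                                   max_codepoint=90),
                            min_size=1, max_size=4),
           seq=st.integers(1, 99999),
           path=st.lists(st.integers(1, 99), max_size=4))
    def test_parse_render_round_trip(self, initials, seq, path):
        label = SampleLabel(initials, seq, tuple(path))
        assert parse_label(label.render()) == label


class TestCas:
    def test_check_digit_oracle(self):
        # brute-force: enumerate all check digits for 64-17-?; only 5 passes
        valid = [d for d in range(10) if cas_check_digit_ok(f"64-17-{d}")]
        assert valid == [5]

    def test_assign_valid_cas_from_molecule_list(self, store, ethanol):
        m = register_molecule(ethanol, store)
        store.execute("UPDATE molecules SET cas_numbers=? WHERE id=?",
                      ('["64-17-5"]', m.id))
        s = create_sample(m, "PT", store)
        s = assign_cas(s, "64-17-5", store)
        assert s.selected_cas == "64-17-5"

    def test_cas_absent_from_molecule_rejected(self, store, ethanol):
        m = register_molecule(ethanol, store)
        s = create_sample(m, "PT", store)
        with pytest.raises(ValidationError, match="not among"):
            assign_cas(s, "64-17-5", store)

    def test_bad_check_digit_rejected(self, store, ethanol):
        m = register_molecule(ethanol, store)
        s = create_sample(m, "PT", store)
        with pytest.raises(ValidationError, match="check-digit"):
            assign_cas(s, "64-17-6", store)


class TestListView:
    def test_reagent_only_samples_hidden_by_default(self, store, ethanol,
                                                    water, propanol):
        from elnkit import stoichiometry as stoi
        ms = [register_molecule(g, store) for g in (ethanol, water, propanol)]
        samples = [create_sample(m, "PT", store) for m in ms]
        r = stoi.new_reaction("PT", store)
        stoi.add_participant(r, samples[0].id, "starting_material")
        stoi.add_participant(r, samples[1].id, "reagent")
        stoi.add_participant(r, samples[2].id, "product")
        stoi.save_reaction(r, store)
        visible = {row["label"] for row in list_samples(store)}
        assert visible == {"PT-1", "PT-3"}
        everything = {row["label"]
                      for row in list_samples(store, include_reagents=True)}
        assert everything == {"PT-1", "PT-2", "PT-3"}

    def test_empty_collection_lists_nothing(self, store):
        from elnkit.collections import create_collection
        c = create_collection("PT", "empty", store)
        assert list_samples(store, collection_id=c.id) == []

    def test_summary_carries_presence_flags_and_analyses(self, store,
                                                         ethanol):
        m = register_molecule(ethanol, store)
        s = create_sample(m, "PT", store)
        record = ExternalRecord(source="pubchem", key=m.key, cid="702",
                                hit=True, query_date="2017-09-25")
        enrich_molecule(m, record, store)
        registry.add_analysis(s, "NMR", store, status="confirmed")
        summary = list_samples(store)[0]
        assert summary["external_db"] == {"pubchem": True}
        assert summary["analyses"] == ["confirmed"]
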