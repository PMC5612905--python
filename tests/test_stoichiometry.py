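"""Amount conversions, equivalents, yield, concentrations, temperature."""

import pytest
from hypothesis import given, settings, strategies as st

from elnkit import registry, stoichiometry as stoi
from elnkit.chemgraph import graph_from_smiles
from elnkit.errors import (InsufficientDataError, MissingReferenceError,
                           NotFoundError, ValidationError)
from elnkit.stoichiometry import (AmountTriple, SampleProps, add_participant,
                                  add_solvent, compute_yield,
                                  convert_temperature, equivalents,
                                  from_moles, new_reaction, set_reference,
                                  solvent_concentrations, to_moles)


class TestToMoles:
    def test_mass_route(self):
        n = to_moles(AmountTriple(0.100, "g"), SampleProps(100.0, 1.0))
        assert n == pytest.approx(1.000e-3)

    def test_purity_scales_mass_route(self):
        n = to_moles(AmountTriple(0.100, "g"), SampleProps(100.0, 0.5))
        assert n == pytest.approx(0.500e-3)

    def test_density_volume_route(self):
        n = to_moles(AmountTriple(2.0, "ml"),
                     SampleProps(46.07, 1.0, density=0.789))
        assert n * 1000 == pytest.approx(34.25, abs=0.005)  # mmol, 4 s.f.

    def test_molarity_takes_precedence_and_ignores_purity(self):
        props = SampleProps(46.07, 0.5, density=0.789, molarity=2.0)
        n = to_moles(AmountTriple(5.0, "ml"), props)
        assert n == pytest.approx(0.010)

    def test_volume_without_molarity_or_density(self):
        with pytest.raises(InsufficientDataError) as err:
            to_moles(AmountTriple(1.0, "ml"), SampleProps(46.07))
        assert "molarity" in str(err.value)

    def test_unknown_unit_rejected(self):
        with pytest.raises(ValidationError):
            AmountTriple(1.0, "stone")

    @settings(max_examples=120, deadline=None, derandomize=True)
    @given(value=st.floats(1e-6, 1e3),
           unit=st.sampled_from(["g", "mg", "µg", "ml", "µl", "mol", "mmol"]),
           purity=st.floats(0.1, 1.0))
    def test_round_trip_within_1e9_relative(self, value, unit, purity):
        props = SampleProps(molecular_mass=46.07, purity=purity,
                            density=0.789, molarity=None)
        n = to_moles(AmountTriple(value, unit), props)
        back = from_moles(n, unit, props)
        assert back.value == pytest.approx(value, rel=1e-9)


def _reaction_fixture(store, with_product_real=0.5):
    """1.0 mmol ethanol reference + reagent + product skeleton."""
    eth = registry.register_molecule(graph_from_smiles("CCO", "ethanol"),
                                     store)
    ace = registry.register_molecule(
        graph_from_smiles("CC(=O)O", "acetic acid"), store)
    s_ref = registry.create_sample(eth, "PT", store)
    s_prod = registry.create_sample(ace, "PT", store)
    r = new_reaction("PT", store)
    add_participant(r, s_ref.id, "starting_material",
                    target=AmountTriple(1.0, "mmol"),
                    real=AmountTriple(1.0, "mmol"))
    add_participant(r, s_prod.id, "product",
                    real=(AmountTriple(with_product_real, "mmol")
                          if with_product_real is not None else None))
    return r, s_ref, s_prod


class TestReference:
    def test_sole_starting_material_is_default_reference(self, store):
        r, *_ = _reaction_fixture(store)
        assert equivalents(r, "T", store)[0] == 1.0

    def test_two_starting_materials_need_explicit_reference(self, store):
        r, s_ref, _ = _reaction_fixture(store)
        add_participant(r, s_ref.id, "starting_material",
                        target=AmountTriple(2.0, "mmol"))
        with pytest.raises(MissingReferenceError):
            equivalents(r, "T", store)
        set_reference(r, r.participants[0])
        assert equivalents(r, "T", store)[0] == 1.0

    def test_reagent_may_be_reference(self, store):
        r, s_ref, _ = _reaction_fixture(store)
        add_participant(r, s_ref.id, "reagent",
                        target=AmountTriple(2.0, "mmol"))
        set_reference(r, r.participants[2])
        eq = equivalents(r, "T", store)
        assert eq[2] == 1.0 and eq[0] == pytest.approx(0.5)

    def test_product_cannot_be_reference(self, store):
        r, *_ = _reaction_fixture(store)
        with pytest.raises(ValidationError):
            set_reference(r, r.participants[1])


class TestEquivalents:
    def test_reagent_double_the_reference(self, store):
        r, s_ref, _ = _reaction_fixture(store)
        add_participant(r, s_ref.id, "reagent",
                        target=AmountTriple(2.0, "mmol"))
        assert equivalents(r, "T", store)[2] == pytest.approx(2.0)

    def test_missing_amount_maps_to_absent_not_zero(self, store):
        r, s_ref, _ = _reaction_fixture(store)
        add_participant(r, s_ref.id, "reagent")
        assert equivalents(r, "T", store)[2] is None

    def test_scale_invariance(self, store):
        r, s_ref, _ = _reaction_fixture(store)
        add_participant(r, s_ref.id, "reagent",
                        target=AmountTriple(2.0, "mmol"))
        before = equivalents(r, "T", store)
        for p in r.participants:
            if p.target:
                object.__setattr__(p, "target",
                                   AmountTriple(p.target.value * 7.3,
                                                p.target.unit))
        after = equivalents(r, "T", store)
        for k in before:
            if before[k] is not None:
                assert after[k] == pytest.approx(before[k], rel=1e-12)

    def test_mass_and_mole_denominated_inputs_agree(self, store):
        eth = registry.register_molecule(graph_from_smiles("CCO"), store)
        s = registry.create_sample(eth, "PT", store)
        mw = eth.average_mass
        r1 = new_reaction("PT", store)
        add_participant(r1, s.id, "starting_material",
                        target=AmountTriple(1.0, "mmol"))
        add_participant(r1, s.id, "reagent",
                        target=AmountTriple(2.0, "mmol"))
        r2 = new_reaction("PT", store)
        add_participant(r2, s.id, "starting_material",
                        target=AmountTriple(mw * 1.0, "mg"))
        add_participant(r2, s.id, "reagent",
                        target=AmountTriple(mw * 2.0, "mg"))
        assert equivalents(r1, "T", store)[1] == pytest.approx(
            equivalents(r2, "T", store)[1], rel=1e-9)

    def test_sample_edits_apply_instantly(self, store):
        """A purity edit on the reference sample changes the computed
        equivalents on the very next call, with no re-save step."""
        r, s_ref, _ = _reaction_fixture(store)
        mw = registry.get_molecule(store, 1).average_mass
        # mass-denominated reference, mole-denominated reagent
        r.participants[0].target = AmountTriple(mw, "mg")  # 1.0 mmol at p=1
        add_participant(r, s_ref.id, "reagent",
                        target=AmountTriple(1.0, "mmol"))
        eq_pure = equivalents(r, "T", store)[2]
        assert eq_pure == pytest.approx(1.0, rel=1e-9)
        registry.update_sample(registry.get_sample(store, s_ref.id), store,
                               purity=0.5)
        # reference moles halve, so the reagent's equivalents double
        assert equivalents(r, "T", store)[2] == pytest.approx(2.0, rel=1e-9)


class TestYield:
    def test_half_product_is_fifty_percent(self, store):
        r, *_ = _reaction_fixture(store, with_product_real=0.5)
        y = compute_yield(r, store)[1]
        assert y.percent == 50.0 and not y.over_yield

    def test_missing_real_amount_is_absent(self, store):
        r, *_ = _reaction_fixture(store, with_product_real=None)
        assert compute_yield(r, store)[1] is None

    def test_over_yield_reported_and_flagged(self, store):
        r, *_ = _reaction_fixture(store, with_product_real=1.2)
        y = compute_yield(r, store)[1]
        assert y.percent == 120.0 and y.over_yield

    def test_reference_falls_back_to_target_products_do_not(self, store):
        r, *_ = _reaction_fixture(store, with_product_real=0.5)
        r.participants[0].real = None  # plan only for the reference
        y = compute_yield(r, store)[1]
        assert y.percent == 50.0

    def test_yield_values_are_immutable(self):
        with pytest.raises(Exception):
            stoi.YieldValue(50.0, False).percent = 90.0


class TestSolvents:
    def test_one_mmol_in_ten_ml_is_tenth_molar(self, store):
        r, *_ = _reaction_fixture(store)
        add_solvent(r, "THF", volume=AmountTriple(10.0, "ml"))
        assert solvent_concentrations(r, store)[0] == pytest.approx(0.1)

    def test_multiple_solvent_volumes_sum(self, store):
        r, *_ = _reaction_fixture(store)
        r.participants[0].target = AmountTriple(2.0, "mmol")
        add_solvent(r, "THF", volume=AmountTriple(5.0, "ml"))
        add_solvent(r, "THF", volume=AmountTriple(5.0, "ml"))
        assert solvent_concentrations(r, store)[0] == pytest.approx(0.2)

    def test_no_solvent_rows_all_absent(self, store):
        r, *_ = _reaction_fixture(store)
        conc = solvent_concentrations(r, store)
        assert all(v is None for v in conc.values())

    def test_preset_carries_density_and_mw(self, store):
        r, *_ = _reaction_fixture(store)
        p = add_solvent(r, "THF")
        assert p.solvent_density == pytest.approx(0.889)
        assert p.solvent_mw == pytest.approx(72.11)

    def test_unknown_preset(self, store):
        r, *_ = _reaction_fixture(store)
        with pytest.raises(NotFoundError):
            add_solvent(r, "xyz")


class TestTemperature:
    @pytest.mark.parametrize("value, src, dst, expected", [
        (25.0, "°C", "K", 298.15),
        (32.0, "°F", "°C", 0.0),
        (0.0, "K", "°C", -273.15),
        (100.0, "°C", "°F", 212.0),
    ])
    def test_affine_conversions(self, value, src, dst, expected):
        assert convert_temperature(value, src, dst) \
            == pytest.approx(expected, abs=1e-9)

    def test_unknown_unit(self):
        with pytest.raises(ValidationError):
            convert_temperature(0.0, "R", "K")


class TestReactionLabels:
    def test_per_user_reaction_counter(self, store):
        assert stoi.reaction_label("PT", store) == "PT-R1"
        assert stoi.reaction_label("PT", store) == "PT-R2"
        assert stoi.reaction_label("AB", store) == "AB-R1"

    def test_product_short_labels_follow_assignment_order(self, store):
        r, s_ref, s_prod = _reaction_fixture(store)
        eth2 = registry.get_molecule(store, 1)
        s_prod2 = registry.create_sample(eth2, "PT", store)
        add_participant(r, s_prod2.id, "product")
        stoi.save_reaction(r, store)
        assert registry.get_sample(store, s_prod.id).short_label \
            == f"{r.label}-1"
        assert registry.get_sample(store, s_prod2.id).short_label \
            == f"{r.label}-2"
        # stable across reload
        reloaded = stoi.load_reaction(store, r.id)
        assert stoi.product_short_labels(reloaded) \
            == stoi.product_short_labels(r)

    def test_status_and_references_validation(self, store):
        r, *_ = _reaction_fixture(store)
        stoi.set_status(r, "successful")
        with pytest.raises(ValidationError):
            stoi.set_status(r, "maybe")
        stoi.add_reference_link(r, "a paper", "https://doi.org/10/abc")
        with pytest.raises(ValidationError):
            stoi.add_reference_link(r, "bad", "not a url")
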