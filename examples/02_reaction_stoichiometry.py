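"""Plan a reaction and let the calculator derive everything.

Equivalents are mole ratios against the reference material (always
1.0); the yield is computed from real amounts and cannot be typed in;
reagent concentrations come from the combined solvent volume.
"""

from elnkit import (AmountTriple, Store, add_solvent, compute_yield,
                    create_sample, equivalents, graph_from_smiles,
                    new_reaction, register_molecule, solvent_concentrations)
from elnkit.stoichiometry import add_participant

store = Store()
ethanol = register_molecule(graph_from_smiles("CCO", "ethanol"), store)
acid = register_molecule(graph_from_smiles("CC(=O)O", "acetic acid"), store)
ester = register_molecule(
    graph_from_smiles("CCOC(=O)C", "ethyl acetate"), store)

s_eth = create_sample(ethanol, "PT", store)
s_acid = create_sample(acid, "PT", store)
s_ester = create_sample(ester, "PT", store)

r = new_reaction("PT", store, name="Fischer esterification")
print(f"reaction label: {r.label}")

add_participant(r, s_eth.id, "starting_material",
                target=AmountTriple(1.0, "mmol"),
                real=AmountTriple(1.0, "mmol"))
add_participant(r, s_acid.id, "reagent", target=AmountTriple(2.0, "mmol"))
add_participant(r, s_ester.id, "product", real=AmountTriple(0.5, "mmol"))
add_solvent(r, "THF", volume=AmountTriple(10.0, "ml"))

eq = equivalents(r, "T", store)
print(f"equivalents (T): reference={eq[0]}, acetic acid={eq[1]}")
# the sole starting material is the reference by default: exactly 1.0

y = compute_yield(r, store)[2]
print(f"yield: {y.percent:.1f}%  (over-yield flag: {y.over_yield})")
# 0.5 mmol product from 1.0 mmol reference -> 50.0%, computed, never typed

conc = solvent_concentrations(r, store)
print(f"reference concentration: {conc[0]:.3g} mol/L in 10 ml THF")
# 1.0 mmol in 10 ml -> 0.1 mol/L
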