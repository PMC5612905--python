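"""Register molecules and samples; watch deduplication at work.

A *molecule* is the unique theoretical structure, keyed by its
structure key (InChIKey via the toolkit); a *sample* is a physical
batch of it.  Registering the same structure twice — even atom-permuted
— returns the existing molecule.
"""

from elnkit import (Store, create_sample, graph_from_smiles,
                    register_molecule)

store = Store()  # in-memory; pass a path for a persistent notebook

ethanol = graph_from_smiles("CCO", "ethanol")
m1 = register_molecule(ethanol, store)
print(f"registered: molecule {m1.id}  {m1.sum_formula}  "
      f"{m1.average_mass:.4f} g/mol  key={m1.key.value}")

# the same structure with atoms listed in another order deduplicates
m2 = register_molecule(ethanol.permuted([2, 0, 1]), store)
print(f"re-registered permuted copy -> molecule {m2.id} "
      f"(same id: {m1.id == m2.id})")

# a constitutional isomer is a different molecule
dme = graph_from_smiles("COC", "dimethyl ether")
m3 = register_molecule(dme, store)
print(f"dimethyl ether -> molecule {m3.id} (new entry)")

# samples are labelled per user: initials + running number
s1 = create_sample(m1, "PT", store)
s2 = create_sample(m1, "PT", store, purity=0.95)
print(f"samples of ethanol: {s1.rendered_label}, {s2.rendered_label} "
      f"(purity {s2.purity})")
# Both samples point at one molecule: the count of molecules stays 2
# while samples accumulate — that is the central data-model split.
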