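"""Text, similarity and substructure search over a registered store."""

from elnkit import (Store, create_sample, graph_from_smiles,
                    register_molecule, similarity_search,
                    substructure_search, text_search, trigram_similarity)

store = Store()
for smiles, name in [("CCO", "ethanol"), ("CO", "methanol"),
                     ("CCCO", "1-propanol"), ("CC(=O)O", "acetic acid"),
                     ("c1ccccc1", "benzene")]:
    m = register_molecule(graph_from_smiles(smiles, name), store)
    create_sample(m, "PT", store)

# trigram text search: tolerant of partial words and typos
print(f"trigram('ethanol','methanol') = "
      f"{trigram_similarity('ethanol', 'methanol'):.3f}")
hits = text_search("ethanl", store)  # note the typo
print("text search 'ethanl' ->",
      [(sid, round(score, 2)) for sid, score in hits["samples"]])

# fingerprint similarity (Tanimoto over hashed 2-7 atom paths)
query = graph_from_smiles("CCO")
for mol_id, score in similarity_search(query, store, threshold=0.1):
    print(f"similar to ethanol: molecule {mol_id}  tanimoto={score:.3f}")

# substructure: bit screen then exact VF2 verification
sub_hits = substructure_search(graph_from_smiles("CO"), store)
print(f"molecules containing a C-O unit: {sub_hits}")
# benzene (aromatic ring, no C-O single bond) is correctly absent
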