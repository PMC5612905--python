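"""Export samples to SDF, reimport them elsewhere, enrich from fixtures."""

from pathlib import Path

from elnkit import (ExportSelection, Store, create_sample, enrich_molecule,
                    export_sdf, graph_from_smiles, import_sdf,
                    parse_enrichment_response, register_molecule)

store = Store()
samples = []
for smiles, name in [("CCO", "ethanol"), ("CC(=O)O", "acetic acid")]:
    m = register_molecule(graph_from_smiles(smiles, name), store)
    samples.append(create_sample(m, "PT", store, purity=0.97,
                                 description=f"stock of {name}"))

sel = ExportSelection(("label", "formula", "average_mass", "purity",
                       "description"))
sdf = export_sdf(samples, sel, store)
print(f"SDF export: {sdf.count('$$$$')} records, "
      f"{sdf.count('> <')} data items total")

other = Store()  # a colleague's notebook
report = import_sdf(sdf, other, user_initials="AB")
print(f"import: {report.created_molecules} new molecules, "
      f"{report.created_samples} samples, "
      f"{report.skipped_records} skipped")

# enrichment from a canned exact-structure response (no network needed)
fixture = Path(__file__).parent.parent / "tests" / "data" / "enrichment" \
    / "ethanol.json"
record = parse_enrichment_response(fixture.read_text())
m = register_molecule(graph_from_smiles("CCO", "ethanol"), store)
m = enrich_molecule(m, record, store)
print(f"enriched ethanol: cid={m.external_refs['pubchem']['identifier']}, "
      f"CAS candidates={m.cas_numbers}")
# all CAS candidates are kept on the molecule; a sample then selects one
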