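# elnkit

A headless Python implementation of the chemistry core of an electronic
lab notebook (ELN), for chemists and tool builders who want ELN
semantics — compound registration, reaction bookkeeping, chemical
search, controlled sharing — as an importable library with a small CLI,
without a web stack.

## The model

The data model rests on the molecule/sample split:

- a **molecule** is the unique theoretical structure. Its identity is a
  *structure key*: the InChIKey of the connection table (delegated to
  RDKit), or a built-in canonical graph key where no toolkit is wanted.
  Registration deduplicates on this key — a structure drawn twice, in
  any atom order, is one molecule.
- a **sample** is a physical batch of one molecule, with its own
  molfile, purity *p* ∈ (0, 1], density, amounts and a genealogical
  label `INITIALS-n[-b₁[-b₂…]]` (`PT-3`, first split `PT-3-1`, its
  split `PT-3-1-1`).

On top of that sit:

- **stoichiometry** — for a reaction with reference material *r*,
  equivalents are mole ratios `eqᵢ = nᵢ / n_r` (the reference is
  exactly 1.0); yield is `100 · n_product(real) / n_r` percent and is a
  derived quantity with no setter; amount conversions follow
  `n = m·p / M` (mass), `n = V·c` (molarity) or `n = V·ρ·p / M`
  (density), and reagent concentration is `n / ΣV_solvent`.
- **search** — pg_trgm-style trigram similarity `|A∩B| / |A∪B|` for
  text; a path-based fingerprint (all linear 2–7-atom fragments hashed
  by FNV-1a into 1024 bits) with Tanimoto similarity for structures;
  substructure search screens by bit containment and verifies by VF2
  subgraph monomorphism, so hits are exact.
- **collections & sharing** — a snapshot share fixes the element set;
  a synchronized share stays live; permissions form a cumulative ladder
  read < write < share < delete < import elements < take ownership,
  and detail levels 0–3 restrict which fields a recipient sees.
- **interchange** — SDF and XLSX export/import with a user-chosen field
  selection, and an exact-structure (InChIKey) enrichment contract
  tested against canned JSON fixtures.
- **codes** — UUID-v4 tracking for samples, reactions and analyses;
  QR (full UUID) and truncated Code128 barcode (8-hex prefix) payloads;
  printable SVG label sheets; scan-to-element resolution.

Everything persists in a single-file sqlite store.

## Worked example

```python
from elnkit import (AmountTriple, Store, create_sample, compute_yield,
                    equivalents, graph_from_smiles, new_reaction,
                    register_molecule, solvent_concentrations, add_solvent)
from elnkit.stoichiometry import add_participant

store = Store()
ethanol = register_molecule(graph_from_smiles("CCO", "ethanol"), store)
ester = register_molecule(graph_from_smiles("CCOC(=O)C", "ethyl acetate"), store)
s_eth, s_est = create_sample(ethanol, "PT", store), create_sample(ester, "PT", store)

r = new_reaction("PT", store)
add_participant(r, s_eth.id, "starting_material",
                target=AmountTriple(1.0, "mmol"), real=AmountTriple(1.0, "mmol"))
add_participant(r, s_est.id, "product", real=AmountTriple(0.5, "mmol"))
add_solvent(r, "THF", volume=AmountTriple(10.0, "ml"))

print(equivalents(r, "T", store)[0])          # 1.0
print(compute_yield(r, store)[1].percent)     # 50.0
print(solvent_concentrations(r, store)[0])    # 0.1
```

The three numbers are the reference's equivalents (1.0 by definition),
the computed yield (0.5 mmol obtained from a 1.0 mmol reference →
50.0 %), and the reference's concentration in the combined solvent
volume (1.0 mmol in 10 ml → 0.1 mol/L).

The `examples/` directory holds one short narrative script per
capability (registration/dedup, stoichiometry, search, sharing and
codes, interchange); each prints what it computes and what the numbers
mean. The same functionality is reachable from the shell via the
`elnkit` command (`elnkit --help`).

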