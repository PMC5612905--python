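# Methods

This note records the models, conventions and numerical choices behind
elnkit, the reasoning where the design was genuinely open, and what the
synthetic fixtures do and do not demonstrate.

## Molecular graphs and the molfile dialect

The structural substrate is a labelled undirected graph: atoms carry
element, formal charge, an aromatic flag and an optional explicit-H
assertion; bonds carry order 1, 2, 3 or *aromatic*. Only the MDL V2000
connection table is read and written; V3000 input is rejected with a
clear error. The choice keeps the parser small, testable and adequate
for bench-scale molecules (V2000 holds up to 999 atoms; a capacity
error is raised beyond that). Old-style charge columns are honoured
unless any `M  CHG` line is present, in which case those supersede the
column for the whole block, as the format prescribes. Wedge/hash codes
ride through round trips verbatim but are ignored by keys and
fingerprints: the package does not attempt stereo or tautomer
canonicalisation, and two stereoisomers are the same molecule to it.

**Implicit hydrogens.** MDL default valences (C 4, N 3, O 2, S 2,
halogens 1, P 3, B 3, Si 4) minus the bond-order sum, minus the
magnitude of the formal charge, minus any explicit-H assertion, floored
at 0. An aromatic bond counts 1.5 and the per-atom sum is floored, so a
benzene carbon with two ring bonds gets exactly one hydrogen. Charged
nitrogen is therefore treated like charged carbon (|charge| reduces the
allowance); this is a simplification relative to the `N⁺ → valence 4`
convention of some toolkits and is stated here because it affects
formulas of charged species. Hydrogen atoms never receive implicit
hydrogens.

**Masses.** Static tables of standard atomic weights and most-abundant
isotope masses ship with the package, so formulas and masses need no
toolkit at run time. Values are reported to 4 decimals (H₂O → 18.0153
average, 18.0106 monoisotopic).

## Structure keys and deduplication

Two backends produce the deduplication key:

- `toolkit` delegates to RDKit and returns the standard InChIKey. This
  is the default and mirrors common registry practice. InChI applies
  its own normalisation (e.g. mobile-hydrogen handling), so a pair of
  distinct connection tables can legitimately share an InChIKey; that
  is a feature of the identifier, not a defect of the registry.
- `fallback` is a self-contained canonical graph key: Morgan-style
  iterative colour refinement from (element, charge, aromatic flag,
  degree, explicit H), followed by individualisation-refinement where
  classes stay ambiguous — each member of the first ambiguous class is
  individualised in turn and the lexicographically smallest canonical
  adjacency string wins; the string is SHA-256-hashed. This key
  distinguishes exactly up to labelled-graph isomorphism, which is the
  property the deduplication tests and the acceptance script check
  against a brute-force isomorphism oracle. Individualisation is
  exponential only on highly symmetric graphs — immaterial at ≤ 16
  heavy atoms.

Both keys are invariant under atom permutation; keys of different
kinds never compare equal.

## Stoichiometry conventions

- Units form three closed dimensions (g/mg/µg, l/ml/µl, mol/mmol) with
  exact power-of-ten scaling.
- Purity is a fraction in (0, 1], default 1.0. It scales mass→mole and
  density-volume→mole conversions; the molarity route ignores it, a
  concentration being read as "of the pure species".
- The reference material carries exactly 1.0 equivalents. The sole
  starting material is the reference by default; with several starting
  materials one must be set explicitly, and products and solvents are
  never eligible. Solvents are excluded from equivalents entirely.
- Real (R) mode: the *reference denominator* may fall back to the
  target amount so a partially recorded run still reports; other
  participants never fall back, and products in particular cannot —
  the yield must reflect measured reality. Yields above 100 % are
  reported and flagged, never clamped.
- Concentrations use target amounts (the table is a planning tool) and
  the summed volume of all solvent rows; with no solvent volume the
  value is absent, not an error. Using real amounts instead would be a
  one-line change; target was chosen and is stated here.
- Nothing derived is stored: equivalents, yields and concentrations
  are recomputed from current sample properties on every call, so a
  density or purity edit is reflected instantly.
- Display contracts (computation is full precision): 4 significant
  figures for amounts, 1 decimal for yield %, 3 significant figures
  for concentrations.

## Search

**Trigram matching.** Text is lower-cased and split into Unicode
alphanumeric words (underscore separates); each word is padded with
two leading and one trailing space and its 3-grams collected; the
similarity is Jaccard overlap, with 0.0 for two empty sets. The default
match threshold is 0.3, mirroring the trigram module the semantics are
modelled on. Searched fields: label, IUPAC name, sum formula, InChI,
canonical SMILES, external label; reactions are returned when any of
their samples hit.

**Fingerprints.** Every simple linear path of 2–7 atoms is encoded as
alternating atom tokens (element + aromatic flag) and bond-order
tokens; the canonical direction is the lexicographically smaller
traversal. Each distinct fragment is hashed by 32-bit FNV-1a modulo the
width (default 1024) and sets one bit. Single atoms contribute no
fragments, so single-atom graphs have empty fingerprints — two empty
fingerprints compare as identical (Tanimoto 1.0), documented here
because the convention is arguable. Determinism across runs and
platforms is guaranteed; bit-compatibility with any external toolkit's
path fingerprints is explicitly not claimed.

**Substructure.** The fingerprint screen (query bits ⊆ candidate bits)
is sound for subgraph *monomorphism*: a true match maps every query
path to an identical path in the target, so no true match is screened
out. Screened candidates are verified with VF2 monomorphism (networkx),
matching atoms on element + aromatic flag and bonds on order with
aromatic ≠ single; a fingerprint-only search would admit false
positives, and exactness was chosen. Aromaticity is perception-free:
rings are aromatic only if the input flags them (molfile bond type 4 /
lowercase SMILES); no aromatiser is implemented, so a Kekulé benzene
and an aromatic-flagged benzene are different query targets — callers
should pick one convention per store (the fixture generator and the
curated set default to aromatic flags).

## Collections, sharing, redaction

Permissions form a cumulative ordered ladder (read < write < share <
delete < import elements < take ownership): the actions are described
as a range, and an ordered model also gives the no-escalation property
a clean statement — a grantee can never issue a grant above their own
level, enforced at share time. Whether "import elements" should
outrank "delete" is not derivable from first principles; the ordering
above is declared, not inferred. Snapshot shares copy the element
references into a frozen collection (the contained elements stay live
and editable per permission); synchronized shares grant access to the
live collection itself. Detail levels are a 4-level cumulative field
map (0 = structure/formula/label, 1 = + properties-tab fields, 2 = +
analysis metadata, 3 = everything); redaction removes fields rather
than blanking them, and composing redactions equals redacting at the
lowest level. Groups are flat member sets; nesting is unsupported.

## Interchange and enrichment

SDF data items are the uppercase snake-case of the field names; the
export field vocabulary (label, molfile, canonical_smiles, inchi,
inchikey, formula, average_mass, exact_mass, cas, purity, density,
description, external_refs) is a deliberate superset of what a
checkbox menu would offer. Workbooks are single-sheet, UTF-8, no
formulas, with molfiles newline-escaped into their cell — maximal
re-import fidelity. Import is fault-isolated per record: a corrupt
record yields a diagnostic, not an abort. Enrichment is modelled as an
exact-structure lookup by InChIKey; responses parse into an immutable
record, a miss is `hit=false` (never an error), all CAS candidates are
retained on the molecule (ill-formed ones flagged, since external data
is stored as received), and a user-edited name is never overwritten.
Live HTTP is deliberately out of the library: the contract is exercised
against canned JSON fixtures whose schema (inchikey/hit/cid/iupac_name/
canonical_smiles/cas/query_date) is documented by the fixtures in
`tests/data/enrichment/`.

## Tracking codes

UUID version 4 per element (samples, reactions, analyses), reproducible
in tests via an injectable RNG. The QR payload is the full UUID; the
truncated barcode is the first 8 hex characters in Code128-B — length
and symbology are this package's declaration, chosen so the 1-D code
stays printable at vial size while 8 hex digits (~4·10⁹ values) keep
accidental collisions negligible at notebook scale. A prefix that does
collide resolves to the candidate list rather than an error or a wrong
element. Label sheets are SVG (vector, deterministic, trivially
embeddable); the QR encoder (byte mode, EC level L, versions 1–5,
single Reed-Solomon block, fixed mask with matching BCH format bits)
and the Code128 encoder are implemented in-repo.

## Synthetic fixtures

The generator grows a random spanning tree over a weighted organic
palette (C-heavy, plus N, O, S, F, Cl, Br), upgrading bonds to double/
triple only where both ends have the free valence, then closes at most
one ring with probability 0.3. Defaults: 2–12 heavy atoms, 20 % of
emitted graphs are atom-permuted duplicates of earlier ones — the load
a registry's deduplication actually faces. Output is deterministic per
seed. The curated set of ~33 named common molecules (solvents, small
alcohols, aromatics) enters through the toolkit from SMILES.

What the fixtures do **not** emulate: stereochemistry, charged species,
isotopes, tautomer-prone functional groups, and molecules beyond 16
heavy atoms. Passing tests therefore demonstrate the graph-level
contracts (dedup, screening soundness, round trips) — not InChI edge
cases on exotic real-world structures.

## Problem sizes and determinism

The test suite and the acceptance script run the properties at the
scales stated in the README (200-graph dedup, 200 screen pairs,
100-molecule ranking, 1,000 string pairs / codes / labels); each
completes in seconds on one CPU. All randomness flows from explicit
seeds (`--seed` in the acceptance script; fixed seeds and derandomised
property tests in the suite).

## Known limitations

- No aromaticity perception, no stereo/tautomer awareness (by scope).
- The implicit-H charge rule under-counts H on positively charged N.
- The fallback key hashes the canonical string; SHA-256 collisions are
  cryptographically negligible but the key is not reversible.
- The permission model is single-store; there is no multi-server
  federation, notification, or conflict resolution beyond
  last-write-wins.
- `list_samples` hides reagent-only samples by joining across reaction
  participants at query time; at very large stores an index or
  materialised role column would be preferable.
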