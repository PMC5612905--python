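"""Molecule and sample registration.

The registry enforces the notebook's central discipline: a *molecule*
is the unique theoretical structure, deduplicated by structure key; a
*sample* is a physical batch of one molecule with its own molfile,
purity and amounts.  Samples carry human-readable labels built from the
owner's initials, a per-user sequence number and a recursive batch path
(``PT-3``, first split ``PT-3-1``, its split ``PT-3-1-1``), so ancestry
is readable straight off the vial.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from . import chemgraph
from .chemgraph import MolecularGraph, StructureKey
from .errors import IntegrityError, NotFoundError, ValidationError
from .store import Store, dumps, loads

_CAS_RE = re.compile(r"^\d{2,7}-\d{2}-\d$")
_LABEL_RE = re.compile(r"^([A-Z]+)-([1-9]\d*)((?:-[1-9]\d*)*)$")


# ---------------------------------------------------------------------------
# CAS registry numbers
# ---------------------------------------------------------------------------


def cas_is_wellformed(cas: str) -> bool:
    return bool(_CAS_RE.match(cas))


def cas_check_digit_ok(cas: str) -> bool:
    """CAS RN checksum: digits weighted by position from the right
    (excluding the check digit), summed mod 10."""
    if not cas_is_wellformed(cas):
        return False
    digits = cas.replace("-", "")
    body, check = digits[:-1], int(digits[-1])
    total = sum(int(d) * w for w, d in enumerate(reversed(body), start=1))
    return total % 10 == check


def validate_cas(cas: str) -> None:
    if not cas_is_wellformed(cas):
        raise ValidationError(f"{cas!r} is not a well-formed CAS number")
    if not cas_check_digit_ok(cas):
        raise ValidationError(f"{cas!r} fails the CAS check-digit rule")


# ---------------------------------------------------------------------------
# domain records
# ---------------------------------------------------------------------------


@dataclass
class Molecule:
    id: int
    key: StructureKey
    molfile: str
    iupac_name: str = ""
    user_named: bool = False
    sum_formula: str = ""
    average_mass: float = 0.0
    exact_mass: float = 0.0
    canonical_smiles: str = ""
    inchi_string: str = ""
    cas_numbers: list[str] = field(default_factory=list)
    external_refs: dict = field(default_factory=dict)


@dataclass
class Sample:
    id: int
    molecule_id: int
    label: "SampleLabel"
    molfile: str
    purity: float = 1.0
    density: float | None = None
    molarity: float | None = None
    selected_cas: str | None = None
    parent_id: int | None = None
    description: str = ""
    location: str = ""
    external_label: str = ""
    short_label: str | None = None

    @property
    def rendered_label(self) -> str:
        return self.label.render()


@dataclass
class Analysis:
    id: int
    sample_id: int
    kind: str
    status: str = "unconfirmed"
    attachments: list[str] = field(default_factory=list)
    uuid: str | None = None


@dataclass(frozen=True)
class SampleLabel:
    """Hyphen-separated sample label: ``INITIALS-seq[-b1[-b2...]]``."""

    initials: str
    seq: int
    batch_path: tuple[int, ...] = ()

    def __post_init__(self):
        if not self.initials or not self.initials.isalpha() \
                or self.initials != self.initials.upper():
            raise ValidationError("initials must be non-empty uppercase letters")
        if self.seq < 1 or any(b < 1 for b in self.batch_path):
            raise ValidationError("sequence and batch numbers are positive")

    def render(self) -> str:
        return "-".join([self.initials, str(self.seq),
                         *map(str, self.batch_path)])

    def child(self, k: int) -> "SampleLabel":
        return SampleLabel(self.initials, self.seq, self.batch_path + (k,))


def parse_label(text: str) -> SampleLabel:
    m = _LABEL_RE.match(text)
    if not m:
        raise ValidationError(f"{text!r} is not a valid sample label")
    initials, seq, batches = m.groups()
    path = tuple(int(p) for p in batches.split("-")[1:]) if batches else ()
    return SampleLabel(initials, int(seq), path)


# ---------------------------------------------------------------------------
# registration and deduplication
# ---------------------------------------------------------------------------


def register_molecule(g: MolecularGraph, store: Store,
                      backend: str = "toolkit") -> Molecule:
    """Register a structure, deduplicating on the structure key.

    When the key already exists the stored molecule is returned
    unchanged; otherwise a new entry is created with computed formula
    and masses, and canonical SMILES / InChI backfilled from the
    toolkit where available.
    """
    key = chemgraph.structure_key(g, backend=backend)
    row = store.one("SELECT * FROM molecules WHERE key_value=? AND key_kind=?",
                    (key.value, key.kind))
    if row:
        return _molecule_from_row(row)
    smiles = inchi = ""
    if backend == "toolkit":
        smiles = chemgraph.canonical_smiles(g) or ""
        inchi = chemgraph.inchi_string(g) or ""
    cur = store.execute(
        "INSERT INTO molecules(key_kind, key_value, molfile, iupac_name,"
        " sum_formula, average_mass, exact_mass, canonical_smiles,"
        " inchi_string) VALUES(?,?,?,?,?,?,?,?,?)",
        (key.kind, key.value, chemgraph.write_molfile(g), g.name,
         chemgraph.molecular_formula(g), chemgraph.average_mass(g),
         chemgraph.monoisotopic_mass(g), smiles, inchi))
    return get_molecule(store, cur.lastrowid)


def get_molecule(store: Store, molecule_id: int) -> Molecule:
    row = store.one("SELECT * FROM molecules WHERE id=?", (molecule_id,))
    if row is None:
        raise NotFoundError(f"no molecule with id {molecule_id}")
    return _molecule_from_row(row)


def _molecule_from_row(row) -> Molecule:
    return Molecule(
        id=row["id"],
        key=StructureKey(row["key_kind"], row["key_value"]),
        molfile=row["molfile"],
        iupac_name=row["iupac_name"] or "",
        user_named=bool(row["user_named"]),
        sum_formula=row["sum_formula"] or "",
        average_mass=row["average_mass"],
        exact_mass=row["exact_mass"],
        canonical_smiles=row["canonical_smiles"] or "",
        inchi_string=row["inchi_string"] or "",
        cas_numbers=loads(row["cas_numbers"], []),
        external_refs=loads(row["external_refs"], {}),
    )


def set_molecule_name(m: Molecule, name: str, store: Store) -> Molecule:
    """User-supplied name; protected from later enrichment overwrites."""
    store.execute("UPDATE molecules SET iupac_name=?, user_named=1 WHERE id=?",
                  (name, m.id))
    return get_molecule(store, m.id)


def enrich_molecule(m: Molecule, record, store: Store) -> Molecule:
    """Fold an external exact-structure record into the molecule.

    All candidate CAS numbers are retained (ill-formed ones are kept but
    flagged in ``external_refs``); a user-edited name is never
    overwritten.  Idempotent for a given record.
    """
    if record.key.value != m.key.value:
        raise IntegrityError(
            f"record key {record.key.value} does not match molecule key "
            f"{m.key.value}")
    m = get_molecule(store, m.id)
    cas = list(m.cas_numbers)
    invalid = []
    for number in record.cas_numbers:
        if number not in cas:
            cas.append(number)
        if not cas_check_digit_ok(number):
            invalid.append(number)
    refs = dict(m.external_refs)
    refs[record.source] = {
        "identifier": record.cid,
        "hit": record.hit,
        "hit_count": 1 if record.hit else 0,
        "query_date": record.query_date,
    }
    if invalid:
        refs[record.source]["invalid_cas"] = sorted(set(invalid))
    name = m.iupac_name
    if record.iupac_name and not m.user_named:
        name = record.iupac_name
    smiles = m.canonical_smiles or (record.canonical_smiles or "")
    store.execute(
        "UPDATE molecules SET iupac_name=?, canonical_smiles=?, cas_numbers=?,"
        " external_refs=? WHERE id=?",
        (name, smiles, dumps(cas), dumps(refs), m.id))
    return get_molecule(store, m.id)


# ---------------------------------------------------------------------------
# samples
# ---------------------------------------------------------------------------

_SAMPLE_FIELDS = ("purity", "density", "molarity", "description", "location",
                  "external_label", "molfile")


def create_sample(m: Molecule, user_initials: str, store: Store,
                  **overrides) -> Sample:
    """Create a physical sample of a registered molecule.

    The label is the user's initials plus the next value of their
    per-user sample counter; the sample starts with the molecule's
    molfile but owns its copy thereafter.
    """
    initials = user_initials.upper()
    fields = {"purity": 1.0, "density": None, "molarity": None,
              "description": "", "location": "", "external_label": "",
              "molfile": m.molfile}
    unknown = set(overrides) - set(_SAMPLE_FIELDS)
    if unknown:
        raise ValidationError(f"unknown sample fields {sorted(unknown)}")
    fields.update(overrides)
    _check_purity(fields["purity"])
    label = SampleLabel(initials, store.next_counter(initials, "sample"))
    cur = store.execute(
        "INSERT INTO samples(molecule_id, initials, seq, batch_path, label,"
        " molfile, purity, density, molarity, description, location,"
        " external_label) VALUES(?,?,?,?,?,?,?,?,?,?,?,?)",
        (m.id, initials, label.seq, dumps([]), label.render(),
         fields["molfile"], fields["purity"], fields["density"],
         fields["molarity"], fields["description"], fields["location"],
         fields["external_label"]))
    return get_sample(store, cur.lastrowid)


def _check_purity(purity: float) -> None:
    if not (0.0 < purity <= 1.0):
        raise ValidationError(f"purity must lie in (0, 1], got {purity}")


def derive_child_sample(parent: Sample, store: Store) -> Sample:
    """Split a batch: the child's label extends the parent's with the
    next batch ordinal, and molecule, purity and molfile are inherited."""
    parent = get_sample(store, parent.id)
    n_children = store.one(
        "SELECT COUNT(*) AS n FROM samples WHERE parent_id=?", (parent.id,))["n"]
    label = parent.label.child(n_children + 1)
    cur = store.execute(
        "INSERT INTO samples(molecule_id, initials, seq, batch_path, label,"
        " molfile, purity, density, molarity, selected_cas, parent_id)"
        " VALUES(?,?,?,?,?,?,?,?,?,?,?)",
        (parent.molecule_id, label.initials, label.seq,
         dumps(list(label.batch_path)), label.render(), parent.molfile,
         parent.purity, parent.density, parent.molarity, parent.selected_cas,
         parent.id))
    return get_sample(store, cur.lastrowid)


def get_sample(store: Store, sample_id: int) -> Sample:
    row = store.one("SELECT * FROM samples WHERE id=?", (sample_id,))
    if row is None:
        raise NotFoundError(f"no sample with id {sample_id}")
    return _sample_from_row(row)


def _sample_from_row(row) -> Sample:
    label = SampleLabel(row["initials"], row["seq"],
                        tuple(loads(row["batch_path"], [])))
    return Sample(
        id=row["id"], molecule_id=row["molecule_id"], label=label,
        molfile=row["molfile"], purity=row["purity"], density=row["density"],
        molarity=row["molarity"], selected_cas=row["selected_cas"],
        parent_id=row["parent_id"], description=row["description"],
        location=row["location"], external_label=row["external_label"],
        short_label=row["short_label"])


def update_sample(s: Sample, store: Store, **changes) -> Sample:
    unknown = set(changes) - set(_SAMPLE_FIELDS)
    if unknown:
        raise ValidationError(f"unknown sample fields {sorted(unknown)}")
    if "purity" in changes:
        _check_purity(changes["purity"])
    if "molfile" in changes:
        g = chemgraph.parse_molfile(changes["molfile"])
        m = get_molecule(store, s.molecule_id)
        backend = "fallback" if m.key.kind == "fallback" else "toolkit"
        if chemgraph.structure_key(g, backend=backend).value != m.key.value:
            raise IntegrityError(
                "sample molfile must keep the molecule's structure key; "
                "register a new molecule for a different structure")
    sets = ", ".join(f"{k}=?" for k in changes)
    store.execute(f"UPDATE samples SET {sets} WHERE id=?",
                  (*changes.values(), s.id))
    return get_sample(store, s.id)


def assign_cas(s: Sample, cas: str, store: Store) -> Sample:
    """Pick one of the molecule's stored CAS numbers for this sample."""
    validate_cas(cas)
    m = get_molecule(store, s.molecule_id)
    if cas not in m.cas_numbers:
        raise ValidationError(
            f"{cas} is not among the molecule's CAS numbers {m.cas_numbers}")
    store.execute("UPDATE samples SET selected_cas=? WHERE id=?", (cas, s.id))
    return get_sample(store, s.id)


def add_analysis(s: Sample, kind: str, store: Store,
                 status: str = "unconfirmed",
                 attachments: list[str] | None = None) -> Analysis:
    if status not in ("confirmed", "unconfirmed"):
        raise ValidationError("analysis status is confirmed or unconfirmed")
    cur = store.execute(
        "INSERT INTO analyses(sample_id, kind, status, attachments)"
        " VALUES(?,?,?,?)",
        (s.id, kind, status, dumps(attachments or [])))
    row = store.one("SELECT * FROM analyses WHERE id=?", (cur.lastrowid,))
    return Analysis(row["id"], row["sample_id"], row["kind"], row["status"],
                    loads(row["attachments"], []), row["uuid"])


# ---------------------------------------------------------------------------
# list views
# ---------------------------------------------------------------------------


def list_samples(store: Store, collection_id: int | None = None,
                 include_reagents: bool = False) -> list[dict]:
    """Sample list view.

    By default, samples whose only reaction role is *reagent* are
    hidden — repeatedly used standard reagents would otherwise crowd the
    list.  Each summary carries external-database presence flags and the
    sample's analysis statuses.
    """
    if collection_id is None:
        rows = store.query("SELECT * FROM samples ORDER BY id")
    else:
        rows = store.query(
            "SELECT s.* FROM samples s JOIN collection_elements ce"
            " ON ce.kind='sample' AND ce.element_id=s.id"
            " WHERE ce.collection_id=? ORDER BY s.id", (collection_id,))
    out = []
    for row in rows:
        roles = {
            r["role"] for r in store.query(
                "SELECT DISTINCT role FROM participants WHERE sample_id=?",
                (row["id"],))
        }
        if not include_reagents and roles == {"reagent"}:
            continue
        mol = store.one("SELECT * FROM molecules WHERE id=?",
                        (row["molecule_id"],))
        refs = loads(mol["external_refs"], {})
        statuses = [a["status"] for a in store.query(
            "SELECT status FROM analyses WHERE sample_id=? ORDER BY id",
            (row["id"],))]
        out.append({
            "id": row["id"],
            "label": row["label"],
            "short_label": row["short_label"],
            "molecule_id": row["molecule_id"],
            "formula": mol["sum_formula"],
            "iupac_name": mol["iupac_name"],
            "external_db": {src: bool(info.get("hit"))
                            for src, info in refs.items()},
            "analyses": statuses,
            "roles": sorted(roles),
        })
    return out
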