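"""SDF and spreadsheet interchange, enrichment records, reaction reports.

Export writes one record per sample — the sample's own molfile plus the
user's selection of data fields — either as an SD file (``> <FIELD>``
items, ``$$$$`` terminators) or a single-sheet XLSX workbook.  Import
mirrors export: each record's molecule is registered (deduplicating on
the structure key) and a new sample is created; unparseable records are
skipped with a per-record diagnostic rather than aborting the batch.

Enrichment is modelled as a request/response contract against an
exact-structure lookup keyed by InChIKey; responses (live or canned
JSON fixtures) parse into :class:`ExternalRecord`, and a miss is a
``hit=false`` record, never an error.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

from openpyxl import Workbook, load_workbook

from . import chemgraph, registry, stoichiometry
from .chemgraph import StructureKey
from .errors import MolfileError, ValidationError
from .registry import Molecule, Sample
from .store import Store

EXPORTABLE_FIELDS = (
    "label", "molfile", "canonical_smiles", "inchi", "inchikey", "formula",
    "average_mass", "exact_mass", "cas", "purity", "density", "description",
    "external_refs",
)

#: field name -> SDF data-item name (uppercase snake case)
SDF_ITEM_NAMES = {f: f.upper() for f in EXPORTABLE_FIELDS}
_FIELD_OF_ITEM = {v: k for k, v in SDF_ITEM_NAMES.items()}


@dataclass(frozen=True)
class ExportSelection:
    """Ordered field selection, as ticked in an export checkbox menu."""

    fields: tuple[str, ...]

    def __post_init__(self):
        if not self.fields:
            raise ValidationError("export selection must not be empty")
        unknown = [f for f in self.fields if f not in EXPORTABLE_FIELDS]
        if unknown:
            raise ValidationError(
                f"unknown export fields {unknown}; choose from "
                f"{EXPORTABLE_FIELDS}")


def _field_value(f: str, s: Sample, m: Molecule) -> str:
    if f == "label":
        return s.rendered_label
    if f == "molfile":
        return s.molfile
    if f == "canonical_smiles":
        return m.canonical_smiles
    if f == "inchi":
        return m.inchi_string
    if f == "inchikey":
        return m.key.value if m.key.kind == "inchikey" else ""
    if f == "formula":
        return m.sum_formula
    if f == "average_mass":
        return f"{m.average_mass:.4f}"
    if f == "exact_mass":
        return f"{m.exact_mass:.4f}"
    if f == "cas":
        return s.selected_cas or ";".join(m.cas_numbers)
    if f == "purity":
        return f"{s.purity:g}"
    if f == "density":
        return "" if s.density is None else f"{s.density:g}"
    if f == "description":
        return s.description
    if f == "external_refs":
        return json.dumps(m.external_refs, sort_keys=True)
    raise ValidationError(f"unknown field {f!r}")  # pragma: no cover


# ---------------------------------------------------------------------------
# SDF
# ---------------------------------------------------------------------------


def export_sdf(samples: list[Sample], sel: ExportSelection,
               store: Store) -> str:
    """SD file text: molfile + selected data items per sample."""
    records = []
    for s in samples:
        m = registry.get_molecule(store, s.molecule_id)
        parts = [s.molfile.rstrip("\n")]
        for f in sel.fields:
            parts.append(f"> <{SDF_ITEM_NAMES[f]}>")
            parts.append(_field_value(f, s, m))
            parts.append("")
        parts.append("$$$$")
        records.append("\n".join(parts))
    return "\n".join(records) + ("\n" if records else "")


@dataclass
class ImportReport:
    created_molecules: int = 0
    merged_molecules: int = 0
    created_samples: int = 0
    skipped_records: int = 0
    diagnostics: list[str] = field(default_factory=list)
    sample_ids: list[int] = field(default_factory=list)
    extras: list[dict] = field(default_factory=list)


def _split_sdf(text: str) -> list[str]:
    records, current = [], []
    for line in text.splitlines():
        if line.strip() == "$$$$":
            records.append("\n".join(current))
            current = []
        else:
            current.append(line)
    if any(ln.strip() for ln in current):
        records.append("\n".join(current))
    return records


def _parse_record(record: str) -> tuple[str, dict[str, str]]:
    lines = record.splitlines()
    end = next((i for i, ln in enumerate(lines) if ln.startswith("M  END")),
               None)
    if end is None:
        raise MolfileError("record has no 'M  END' line")
    molfile = "\n".join(lines[:end + 1]) + "\n"
    items: dict[str, str] = {}
    i = end + 1
    while i < len(lines):
        line = lines[i]
        if line.startswith(">"):
            name = line[line.find("<") + 1:line.rfind(">")]
            value_lines = []
            i += 1
            while i < len(lines) and lines[i].strip() != "":
                value_lines.append(lines[i])
                i += 1
            items[name] = "\n".join(value_lines)
        i += 1
    return molfile, items


def import_sdf(text: str, store: Store, user_initials: str = "IMP",
               backend: str = "toolkit") -> ImportReport:
    """Register every record's molecule (deduplicated) and create one
    sample per record.  Recognised data items map onto sample or
    molecule fields; unknown items are kept as per-record extras."""
    report = ImportReport()
    for idx, record in enumerate(_split_sdf(text), start=1):
        try:
            molfile, items = _parse_record(record)
            graph = chemgraph.parse_molfile(molfile)
            before = store.one("SELECT COUNT(*) AS n FROM molecules")["n"]
            mol = registry.register_molecule(graph, store, backend=backend)
            after = store.one("SELECT COUNT(*) AS n FROM molecules")["n"]
            if after > before:
                report.created_molecules += 1
            else:
                report.merged_molecules += 1
            sample = _sample_from_items(mol, molfile, items, store,
                                        user_initials)
            report.created_samples += 1
            report.sample_ids.append(sample.id)
            extras = {k: v for k, v in items.items()
                      if k not in _FIELD_OF_ITEM}
            report.extras.append(extras)
        except Exception as exc:  # record-level fault isolation
            report.skipped_records += 1
            report.diagnostics.append(f"record {idx}: {exc}")
    return report


def _sample_from_items(mol: Molecule, molfile: str, items: dict[str, str],
                       store: Store, user_initials: str) -> Sample:
    overrides: dict = {"molfile": molfile}
    if items.get("PURITY"):
        overrides["purity"] = float(items["PURITY"])
    if items.get("DENSITY"):
        overrides["density"] = float(items["DENSITY"])
    if items.get("DESCRIPTION"):
        overrides["description"] = items["DESCRIPTION"]
    if items.get("LABEL"):
        overrides["external_label"] = items["LABEL"]
    sample = registry.create_sample(mol, user_initials, store, **overrides)
    cas = items.get("CAS", "")
    if cas:
        numbers = [c for c in cas.split(";") if c]
        merged = list(mol.cas_numbers)
        for n in numbers:
            if n not in merged:
                merged.append(n)
        from .store import dumps
        store.execute("UPDATE molecules SET cas_numbers=? WHERE id=?",
                      (dumps(merged), mol.id))
        if numbers and registry.cas_check_digit_ok(numbers[0]):
            sample = registry.assign_cas(sample, numbers[0], store)
    return sample


# ---------------------------------------------------------------------------
# XLSX
# ---------------------------------------------------------------------------

_ESCAPED_NL = "\\n"


def export_table(samples: list[Sample], sel: ExportSelection, store: Store,
                 path: str) -> None:
    """Single-sheet workbook: header = selected field names in order,
    one row per sample; molfiles are newline-escaped into their cell."""
    wb = Workbook()
    ws = wb.active
    ws.title = "samples"
    ws.append(list(sel.fields))
    for s in samples:
        m = registry.get_molecule(store, s.molecule_id)
        row = []
        for f in sel.fields:
            value = _field_value(f, s, m)
            if f == "molfile":
                value = value.replace("\n", _ESCAPED_NL)
            row.append(value)
        ws.append(row)
    wb.save(path)


def import_table(path: str, store: Store, user_initials: str = "IMP",
                 backend: str = "toolkit") -> ImportReport:
    """Mirror of :func:`export_table`.  Needs a structure column
    (``molfile`` preferred, else ``canonical_smiles``)."""
    wb = load_workbook(path, read_only=True)
    ws = wb.active
    rows = ws.iter_rows(values_only=True)
    try:
        header = [str(h) for h in next(rows)]
    except StopIteration:
        raise ValidationError("workbook has no header row") from None
    if "molfile" not in header and "canonical_smiles" not in header:
        raise ValidationError(
            "import needs a structure column: 'molfile' or 'canonical_smiles'")
    report = ImportReport()
    for idx, row in enumerate(rows, start=2):
        try:
            record = {h: ("" if v is None else str(v))
                      for h, v in zip(header, row)}
            if record.get("molfile"):
                molfile = record["molfile"].replace(_ESCAPED_NL, "\n")
                graph = chemgraph.parse_molfile(molfile)
            else:
                graph = chemgraph.graph_from_smiles(record["canonical_smiles"])
                molfile = chemgraph.write_molfile(graph)
            before = store.one("SELECT COUNT(*) AS n FROM molecules")["n"]
            mol = registry.register_molecule(graph, store, backend=backend)
            after = store.one("SELECT COUNT(*) AS n FROM molecules")["n"]
            if after > before:
                report.created_molecules += 1
            else:
                report.merged_molecules += 1
            items = {SDF_ITEM_NAMES[k]: v for k, v in record.items()
                     if k in SDF_ITEM_NAMES and k != "molfile"}
            sample = _sample_from_items(mol, molfile, items, store,
                                        user_initials)
            report.created_samples += 1
            report.sample_ids.append(sample.id)
        except Exception as exc:
            report.skipped_records += 1
            report.diagnostics.append(f"row {idx}: {exc}")
    return report


# ---------------------------------------------------------------------------
# enrichment contract
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ExternalRecord:
    """One exact-structure lookup result from an external database."""

    source: str
    key: StructureKey
    cid: str | None
    iupac_name: str = ""
    canonical_smiles: str = ""
    cas_numbers: tuple[str, ...] = ()
    hit: bool = False
    query_date: str = ""

    def __post_init__(self):
        if not self.hit and self.cid is not None:
            raise ValidationError("a no-hit record cannot carry a cid")


def build_enrichment_query(key: StructureKey) -> dict:
    """Request descriptor for an exact-structure lookup by InChIKey."""
    if key.kind != "inchikey":
        raise ValidationError(
            "live enrichment needs an InChIKey-kind structure key")
    return {
        "service": "pubchem",
        "operation": "exact_structure",
        "namespace": "inchikey",
        "identifier": key.value,
        "url": ("https://pubchem.ncbi.nlm.nih.gov/rest/pug/compound/inchikey/"
                f"{key.value}/property/IUPACName,CanonicalSMILES/JSON"),
    }


def parse_enrichment_response(payload: str | dict) -> ExternalRecord:
    """Parse a canned (or live) response payload into an ExternalRecord.

    Expected JSON shape::

        {"inchikey": ..., "hit": bool, "cid": ..., "iupac_name": ...,
         "canonical_smiles": ..., "cas": [...], "query_date": ...}

    An explicit no-match payload yields ``hit=false`` — never an error.
    """
    if isinstance(payload, str):
        try:
            data = json.loads(payload)
        except json.JSONDecodeError as exc:
            excerpt = payload[:120]
            raise ValidationError(
                f"malformed enrichment payload ({exc}): {excerpt!r}") from None
    else:
        data = payload
    if not isinstance(data, dict) or "inchikey" not in data:
        raise ValidationError(
            f"malformed enrichment payload, no 'inchikey': {str(data)[:120]!r}")
    hit = bool(data.get("hit"))
    return ExternalRecord(
        source=data.get("source", "pubchem"),
        key=StructureKey("inchikey", data["inchikey"]),
        cid=str(data["cid"]) if hit and data.get("cid") is not None else None,
        iupac_name=data.get("iupac_name", ""),
        canonical_smiles=data.get("canonical_smiles", ""),
        cas_numbers=tuple(data.get("cas", [])),
        hit=hit,
        query_date=data.get("query_date", ""))


# ---------------------------------------------------------------------------
# reaction report
# ---------------------------------------------------------------------------


def reaction_report(r: stoichiometry.Reaction, store: Store) -> str:
    """Deterministic structured (markdown) summary of a reaction:
    scheme table with T/R amounts and equivalents, properties,
    references, and per-product analysis subsections."""
    lines = [f"# Reaction {r.label}", ""]
    if r.name:
        lines += [f"**Name:** {r.name}", ""]
    lines += [f"**Status:** {r.status}", ""]
    if r.temperature:
        lines += [f"**Temperature:** {json.dumps(r.temperature, sort_keys=True)}",
                  ""]
    lines += ["## Scheme", "",
              "| # | role | sample | target | real | equiv (T) | yield |",
              "|---|------|--------|--------|------|-----------|-------|"]
    try:
        equiv = stoichiometry.equivalents(r, "T", store)
    except Exception:
        equiv = {}
    try:
        yields = stoichiometry.compute_yield(r, store)
    except Exception:
        yields = {}
    for i, p in enumerate(r.participants):
        name = p.solvent_name or ""
        if p.sample_id is not None:
            name = registry.get_sample(store, p.sample_id).rendered_label
        tgt = _fmt_amount(p.target)
        real = _fmt_amount(p.real)
        eq = equiv.get(i)
        eq_s = "" if eq is None else stoichiometry.format_amount(eq)
        y = yields.get(i)
        y_s = "" if y is None else stoichiometry.format_yield(y)
        lines.append(f"| {i} | {p.role} | {name} | {tgt} | {real} |"
                     f" {eq_s} | {y_s} |")
    lines.append("")
    lines += ["## Properties", ""]
    if r.description:
        lines += [r.description, ""]
    if r.tlc:
        lines += [f"TLC: {r.tlc}", ""]
    lines += ["## References", ""]
    for ref in r.references:
        lines.append(f"- [{ref['title']}]({ref['url']})")
    if not r.references:
        lines.append("(none)")
    lines.append("")
    lines += ["## Analyses", ""]
    for i, p in enumerate(r.participants):
        if p.role != "product" or p.sample_id is None:
            continue
        s = registry.get_sample(store, p.sample_id)
        lines.append(f"### Product {s.rendered_label}")
        rows = store.query(
            "SELECT kind, status FROM analyses WHERE sample_id=? ORDER BY id",
            (p.sample_id,))
        for a in rows:
            lines.append(f"- {a['kind']}: {a['status']}")
        if not rows:
            lines.append("- (no analyses recorded)")
        lines.append("")
    return "\n".join(lines)


def _fmt_amount(a: stoichiometry.AmountTriple | None) -> str:
    if a is None:
        return ""
    return f"{stoichiometry.format_amount(a.value)} {a.unit}"
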