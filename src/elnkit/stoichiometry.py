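"""Reaction model and the stoichiometry calculator.

A reaction holds participants with roles (starting material, reagent,
solvent, product), each with a *target* (planned) and a *real*
(measured) amount.  All derived quantities — equivalents relative to
the reference material, the yield of each product, and reagent
concentrations in the combined solvent volume — are computed on demand
from the current sample properties, never stored, so editing a sample's
density or purity is reflected instantly.  Yield has no setter by
construction: it is a function of recorded reality.

Conventions: the reference material carries exactly 1.0 equivalents;
purity scales mass- and density-derived moles (molarity is taken as a
concentration of the pure species); equivalents and concentrations use
target amounts in T mode; yields use real amounts, with the reference
falling back to its target so a partially recorded run still reports.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime, timezone

from . import chemgraph, registry
from .errors import (InsufficientDataError, MissingReferenceError,
                     NotFoundError, ValidationError)
from .store import Store, dumps, loads

ROLES = ("starting_material", "reagent", "solvent", "product")
REFERENCE_ROLES = ("starting_material", "reagent")
STATUSES = ("planned", "successful", "unsuccessful")

_MASS_UNITS = {"g": 1.0, "mg": 1e-3, "µg": 1e-6, "ug": 1e-6}
_VOLUME_UNITS = {"l": 1.0, "ml": 1e-3, "µl": 1e-6, "ul": 1e-6}
_MOLE_UNITS = {"mol": 1.0, "mmol": 1e-3}

#: named solvent presets: density (g/ml) and molecular weight (g/mol)
SOLVENT_PRESETS: dict[str, tuple[float, float]] = {
    "water": (0.997, 18.02),
    "THF": (0.889, 72.11),
    "DCM": (1.325, 84.93),
    "DMF": (0.944, 73.09),
    "DMSO": (1.100, 78.13),
    "EtOH": (0.789, 46.07),
    "MeOH": (0.791, 32.04),
    "toluene": (0.867, 92.14),
    "MeCN": (0.786, 41.05),
    "EtOAc": (0.902, 88.11),
    "Et2O": (0.713, 74.12),
    "acetone": (0.791, 58.08),
    "chloroform": (1.489, 119.38),
    "hexane": (0.659, 86.18),
}


@dataclass(frozen=True)
class AmountTriple:
    """An amount with its unit; conversions are exact powers of ten
    within a dimension (mass, volume or moles)."""

    value: float
    unit: str

    def __post_init__(self):
        if self.value < 0:
            raise ValidationError("amounts are non-negative")
        if self.dimension is None:
            raise ValidationError(f"unknown unit {self.unit!r}")

    @property
    def dimension(self) -> str | None:
        for name, table in (("mass", _MASS_UNITS), ("volume", _VOLUME_UNITS),
                            ("moles", _MOLE_UNITS)):
            if self.unit in table:
                return name
        return None

    def in_base(self) -> float:
        """Value in the dimension's base unit (g, l, or mol)."""
        table = {"mass": _MASS_UNITS, "volume": _VOLUME_UNITS,
                 "moles": _MOLE_UNITS}[self.dimension]
        return self.value * table[self.unit]


@dataclass(frozen=True)
class SampleProps:
    """The sample-side inputs of an amount conversion."""

    molecular_mass: float | None = None  # g/mol
    purity: float = 1.0                  # fraction in (0, 1]
    density: float | None = None         # g/ml
    molarity: float | None = None        # mol/l


def to_moles(a: AmountTriple, props: SampleProps) -> float:
    """Convert an amount to moles of the pure species.

    mass route:   n = m * purity / MW
    volume route: n = V * molarity           (molarity takes precedence)
                  n = V * density * purity / MW
    mole route:   identity after unit scaling
    """
    if a.dimension == "moles":
        return a.in_base()
    if a.dimension == "mass":
        if props.molecular_mass in (None, 0):
            raise InsufficientDataError(
                "mass-to-mole conversion needs the molecular mass",
                missing="molecular_mass")
        return a.in_base() * props.purity / props.molecular_mass
    # volume
    if props.molarity is not None:
        return a.in_base() * props.molarity
    if props.density is not None:
        if props.molecular_mass in (None, 0):
            raise InsufficientDataError(
                "density route needs the molecular mass",
                missing="molecular_mass")
        grams = a.in_base() * 1000.0 * props.density  # l -> ml * g/ml
        return grams * props.purity / props.molecular_mass
    raise InsufficientDataError(
        "volume given but the sample has neither molarity nor density",
        missing="molarity or density")


def from_moles(n: float, unit: str, props: SampleProps) -> AmountTriple:
    """Inverse of :func:`to_moles` for the same sample properties."""
    probe = AmountTriple(0.0, unit)
    if probe.dimension == "moles":
        base = n
        table = _MOLE_UNITS
    elif probe.dimension == "mass":
        if props.molecular_mass in (None, 0):
            raise InsufficientDataError("needs molecular mass",
                                        missing="molecular_mass")
        base = n * props.molecular_mass / props.purity
        table = _MASS_UNITS
    else:
        if props.molarity is not None:
            base = n / props.molarity
        elif props.density is not None and props.molecular_mass:
            base = n * props.molecular_mass / props.purity \
                / (props.density * 1000.0)
        else:
            raise InsufficientDataError("needs molarity or density",
                                        missing="molarity or density")
        table = _VOLUME_UNITS
    return AmountTriple(base / table[unit], unit)


# ---------------------------------------------------------------------------
# reactions
# ---------------------------------------------------------------------------


@dataclass
class ReactionParticipant:
    sample_id: int | None
    role: str
    target: AmountTriple | None = None
    real: AmountTriple | None = None
    is_reference: bool = False
    # inline properties for preset solvents that have no backing sample
    solvent_name: str | None = None
    solvent_density: float | None = None
    solvent_mw: float | None = None
    id: int | None = None

    def __post_init__(self):
        if self.role not in ROLES:
            raise ValidationError(f"role must be one of {ROLES}")


@dataclass
class Reaction:
    id: int | None = None
    label: str | None = None
    name: str = ""
    status: str = "planned"
    temperature: dict | None = None  # {"value": x, "unit": u} or {"table": [...], "unit": u}
    description: str = ""
    tlc: str = ""
    references: list[dict] = field(default_factory=list)
    participants: list[ReactionParticipant] = field(default_factory=list)
    created_at: str = ""
    updated_at: str = ""

    def by_role(self, role: str) -> list[ReactionParticipant]:
        return [p for p in self.participants if p.role == role]


def reaction_label(user_initials: str, store: Store) -> str:
    """Next systematic reaction label for a user: ``INITIALS-Rn``."""
    initials = user_initials.upper()
    return f"{initials}-R{store.next_counter(initials, 'reaction')}"


def new_reaction(user_initials: str, store: Store, name: str = "") -> Reaction:
    label = reaction_label(user_initials, store)
    now = datetime.now(timezone.utc).isoformat(timespec="seconds")
    cur = store.execute(
        "INSERT INTO reactions(label, name, created_at, updated_at)"
        " VALUES(?,?,?,?)", (label, name, now, now))
    return Reaction(id=cur.lastrowid, label=label, name=name,
                    created_at=now, updated_at=now)


def add_participant(r: Reaction, sample_id: int | None, role: str,
                    target: AmountTriple | None = None,
                    real: AmountTriple | None = None,
                    **solvent_props) -> ReactionParticipant:
    p = ReactionParticipant(sample_id, role, target, real, **solvent_props)
    r.participants.append(p)
    return p


def add_solvent(r: Reaction, source, store: Store | None = None,
                user_initials: str = "XX",
                volume: AmountTriple | None = None) -> ReactionParticipant:
    """Add a solvent row from a named preset, an existing sample id, or
    a molecular graph drawn from scratch."""
    if isinstance(source, str):
        if source not in SOLVENT_PRESETS:
            raise NotFoundError(
                f"unknown solvent preset {source!r}; known: "
                f"{sorted(SOLVENT_PRESETS)}")
        density, mw = SOLVENT_PRESETS[source]
        return add_participant(r, None, "solvent", target=volume,
                               solvent_name=source, solvent_density=density,
                               solvent_mw=mw)
    if isinstance(source, chemgraph.MolecularGraph):
        if store is None:
            raise ValidationError("a store is needed to register a drawn solvent")
        mol = registry.register_molecule(source, store)
        sample = registry.create_sample(mol, user_initials, store)
        return add_participant(r, sample.id, "solvent", target=volume)
    if isinstance(source, int):
        return add_participant(r, source, "solvent", target=volume)
    raise ValidationError("solvent source must be a preset name, a sample id "
                          "or a molecular graph")


def set_reference(r: Reaction, participant: ReactionParticipant) -> Reaction:
    """Mark the participant whose amount defines 1.0 equivalents."""
    if participant.role not in REFERENCE_ROLES:
        raise ValidationError(
            "only a starting material or a reagent can be the reference")
    for p in r.participants:
        p.is_reference = False
    participant.is_reference = True
    return r


def resolve_reference(r: Reaction) -> ReactionParticipant:
    """Explicit reference, else the sole starting material by default."""
    explicit = [p for p in r.participants if p.is_reference]
    if explicit:
        return explicit[0]
    starts = r.by_role("starting_material")
    if len(starts) == 1:
        return starts[0]
    raise MissingReferenceError(
        "no reference material: set one explicitly when there is not "
        "exactly one starting material")


def participant_props(p: ReactionParticipant, store: Store | None) -> SampleProps:
    if p.sample_id is None:
        return SampleProps(molecular_mass=p.solvent_mw,
                           density=p.solvent_density)
    if store is None:
        raise InsufficientDataError("participant references a sample but no "
                                    "store was given", missing="store")
    s = registry.get_sample(store, p.sample_id)
    m = registry.get_molecule(store, s.molecule_id)
    return SampleProps(molecular_mass=m.average_mass, purity=s.purity,
                       density=s.density, molarity=s.molarity)


def participant_moles(p: ReactionParticipant, mode: str,
                      store: Store | None) -> float | None:
    amount = p.real if mode == "R" else p.target
    if amount is None:
        return None
    return to_moles(amount, participant_props(p, store))


def _reference_moles(r: Reaction, mode: str, store: Store | None) -> float:
    ref = resolve_reference(r)
    amount = ref.real if mode == "R" else ref.target
    if mode == "R" and amount is None:
        amount = ref.target  # reference may fall back to the plan
    if amount is None:
        raise InsufficientDataError(
            "the reference material has no amount", missing="reference amount")
    n = to_moles(amount, participant_props(ref, store))
    if n == 0:
        raise InsufficientDataError("reference amount converts to zero moles",
                                    missing="non-zero reference amount")
    return n


def equivalents(r: Reaction, mode: str = "T",
                store: Store | None = None) -> dict[int, float | None]:
    """Mole ratio of each non-solvent participant to the reference.

    Returns a map from participant position (index in ``r.participants``)
    to equivalents; participants without an amount in the requested mode
    map to None.  The reference is exactly 1.0.
    """
    if mode not in ("T", "R"):
        raise ValidationError("mode is 'T' (target) or 'R' (real)")
    ref = resolve_reference(r)
    n_ref = _reference_moles(r, mode, store)
    out: dict[int, float | None] = {}
    for i, p in enumerate(r.participants):
        if p.role == "solvent":
            continue
        if p is ref:
            out[i] = 1.0
            continue
        n = participant_moles(p, mode, store)
        out[i] = None if n is None else n / n_ref
    return out


@dataclass(frozen=True)
class YieldValue:
    percent: float          # to 1 decimal
    over_yield: bool        # >100% reported, flagged, never clamped


def compute_yield(r: Reaction, store: Store | None = None
                  ) -> dict[int, YieldValue | None]:
    """Percent yield per product participant, from real amounts.

    There is deliberately no way to set a yield: the value is always
    100 * n_product(real) / n_reference(real, falling back to target).
    Products with no real amount map to None.
    """
    products = [(i, p) for i, p in enumerate(r.participants)
                if p.role == "product"]
    out: dict[int, YieldValue | None] = {}
    if not products:
        return out
    n_ref = _reference_moles(r, "R", store)
    for i, p in enumerate(r.participants):
        if p.role != "product":
            continue
        n = participant_moles(p, "R", store)
        if n is None:
            out[i] = None
            continue
        pct = round(100.0 * n / n_ref, 1)
        out[i] = YieldValue(percent=pct, over_yield=pct > 100.0)
    return out


def solvent_concentrations(r: Reaction, store: Store | None = None
                           ) -> dict[int, float | None]:
    """Concentration (mol/l) of each non-solvent participant in the
    combined solvent volume, using target amounts.  All None when no
    solvent volume is recorded."""
    total_l = 0.0
    for p in r.by_role("solvent"):
        if p.target is not None and p.target.dimension == "volume":
            total_l += p.target.in_base()
    out: dict[int, float | None] = {}
    for i, p in enumerate(r.participants):
        if p.role == "solvent":
            continue
        if total_l <= 0:
            out[i] = None
            continue
        n = participant_moles(p, "T", store)
        out[i] = None if n is None else n / total_l
    return out


# ---------------------------------------------------------------------------
# temperature
# ---------------------------------------------------------------------------

_TEMP_UNITS = ("°C", "C", "°F", "F", "K")


def convert_temperature(value: float, from_unit: str, to_unit: str) -> float:
    """Exact affine conversion among °C, °F and K."""
    f, t = _canon_temp(from_unit), _canon_temp(to_unit)
    kelvin = {"C": lambda v: v + 273.15,
              "F": lambda v: (v - 32.0) * 5.0 / 9.0 + 273.15,
              "K": lambda v: v}[f](value)
    return {"C": lambda k: k - 273.15,
            "F": lambda k: (k - 273.15) * 9.0 / 5.0 + 32.0,
            "K": lambda k: k}[t](kelvin)


def _canon_temp(unit: str) -> str:
    if unit not in _TEMP_UNITS:
        raise ValidationError(f"unknown temperature unit {unit!r}; "
                              f"use °C, °F or K")
    return unit.lstrip("°")


# ---------------------------------------------------------------------------
# persistence and product labels
# ---------------------------------------------------------------------------


def set_status(r: Reaction, status: str) -> Reaction:
    if status not in STATUSES:
        raise ValidationError(f"status must be one of {STATUSES}")
    r.status = status
    return r


def add_reference_link(r: Reaction, title: str, url: str) -> Reaction:
    """Literature citation: a title plus URL; shape-validated only."""
    if not title:
        raise ValidationError("citation needs a title")
    if not (url.startswith("http://") or url.startswith("https://")
            or url.startswith("doi:")):
        raise ValidationError(f"{url!r} does not look like a URL")
    r.references.append({"title": title, "url": url})
    return r


def save_reaction(r: Reaction, store: Store) -> Reaction:
    """Persist the reaction and stamp product short labels.

    Products get ``<reaction label>-<ordinal>`` in participant order;
    ordinals are stable across reloads because participant positions
    are persisted.
    """
    now = datetime.now(timezone.utc).isoformat(timespec="seconds")
    r.updated_at = now
    store.execute(
        "UPDATE reactions SET name=?, status=?, temperature=?, description=?,"
        " tlc=?, refs=?, updated_at=? WHERE id=?",
        (r.name, r.status, dumps(r.temperature) if r.temperature else None,
         r.description, r.tlc, dumps(r.references), now, r.id))
    store.execute("DELETE FROM participants WHERE reaction_id=?", (r.id,))
    ordinal = 0
    for pos, p in enumerate(r.participants):
        cur = store.execute(
            "INSERT INTO participants(reaction_id, sample_id, role, target,"
            " real, is_reference, solvent_name, solvent_density, solvent_mw,"
            " position) VALUES(?,?,?,?,?,?,?,?,?,?)",
            (r.id, p.sample_id, p.role, _dump_amount(p.target),
             _dump_amount(p.real), int(p.is_reference), p.solvent_name,
             p.solvent_density, p.solvent_mw, pos))
        p.id = cur.lastrowid
        if p.role == "product" and p.sample_id is not None:
            ordinal += 1
            store.execute("UPDATE samples SET short_label=? WHERE id=?",
                          (f"{r.label}-{ordinal}", p.sample_id))
    return r


def load_reaction(store: Store, reaction_id: int) -> Reaction:
    row = store.one("SELECT * FROM reactions WHERE id=?", (reaction_id,))
    if row is None:
        raise NotFoundError(f"no reaction with id {reaction_id}")
    r = Reaction(
        id=row["id"], label=row["label"], name=row["name"],
        status=row["status"],
        temperature=loads(row["temperature"], None),
        description=row["description"], tlc=row["tlc"],
        references=loads(row["refs"], []),
        created_at=row["created_at"], updated_at=row["updated_at"])
    for prow in store.query(
            "SELECT * FROM participants WHERE reaction_id=? ORDER BY position",
            (reaction_id,)):
        r.participants.append(ReactionParticipant(
            sample_id=prow["sample_id"], role=prow["role"],
            target=_load_amount(prow["target"]),
            real=_load_amount(prow["real"]),
            is_reference=bool(prow["is_reference"]),
            solvent_name=prow["solvent_name"],
            solvent_density=prow["solvent_density"],
            solvent_mw=prow["solvent_mw"], id=prow["id"]))
    return r


def product_short_labels(r: Reaction) -> dict[int, str]:
    """Participant index -> ``<reaction label>-<product ordinal>``."""
    out = {}
    ordinal = 0
    for i, p in enumerate(r.participants):
        if p.role == "product":
            ordinal += 1
            out[i] = f"{r.label}-{ordinal}"
    return out


def _dump_amount(a: AmountTriple | None) -> str | None:
    return None if a is None else dumps({"value": a.value, "unit": a.unit})


def _load_amount(text: str | None) -> AmountTriple | None:
    if not text:
        return None
    d = loads(text, None)
    return AmountTriple(d["value"], d["unit"])


# display contracts ---------------------------------------------------------


def format_amount(value: float) -> str:
    """4 significant figures, as shown in reaction tables."""
    return f"{value:.4g}"


def format_concentration(value: float) -> str:
    """3 significant figures (mol/l)."""
    return f"{value:.3g}"


def format_yield(y: YieldValue) -> str:
    flag = " (!)" if y.over_yield else ""
    return f"{y.percent:.1f}%{flag}"
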