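"""Molecular graphs and the MDL V2000 connection-table format.

This module is the structural substrate of the notebook: every sample
and molecule carries a molfile, and everything downstream (formulas,
masses, deduplication keys, fingerprints) is computed from the graph a
molfile parses into.

Two structure-key backends are provided.  ``toolkit`` delegates to RDKit
and yields a standard 27-character InChIKey; ``fallback`` is a
self-contained canonical key built from Morgan-style iterative colour
refinement followed by individualisation, so deduplication still works
where no toolkit is installed.  Both are invariant under atom
permutation; only graphs, not tautomers or stereoisomers, are
distinguished.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace

from . import periodic
from .errors import BackendError, CapacityError, MolfileError, ValidationError

AROMATIC = "aromatic"
BOND_ORDERS = (1, 2, 3, AROMATIC)

# old-style molfile charge column codes (superseded by M CHG)
_CHG_COLUMN = {0: 0, 1: 3, 2: 2, 3: 1, 5: -1, 6: -2, 7: -3}


@dataclass
class Atom:
    """One node of a molecular graph.

    ``explicit_h`` records hydrogens asserted on the atom beyond those
    present as graph nodes; they count toward formulas and masses and
    reduce the implicit-hydrogen allowance.
    """

    index: int
    element: str
    formal_charge: int = 0
    aromatic: bool = False
    explicit_h: int = 0

    def __post_init__(self):
        if self.element not in periodic.KNOWN_ELEMENTS:
            raise ValidationError(f"unknown element symbol {self.element!r}")
        if self.explicit_h < 0:
            raise ValidationError("explicit_h must be >= 0")


@dataclass
class Bond:
    """Undirected edge; ``order`` is 1, 2, 3 or ``"aromatic"``.

    ``stereo`` carries the molfile wedge/hash column verbatim through
    round trips; keys and fingerprints ignore it.
    """

    a: int
    b: int
    order: int | str = 1
    stereo: int = 0

    def __post_init__(self):
        if self.a == self.b:
            raise ValidationError("bond endpoints must differ")
        if self.order not in BOND_ORDERS:
            raise ValidationError(f"bond order must be one of {BOND_ORDERS}")

    @property
    def pair(self) -> tuple[int, int]:
        return (self.a, self.b) if self.a < self.b else (self.b, self.a)

    def numeric_order(self) -> float:
        """Order for valence accounting: aromatic counts 1.5."""
        return 1.5 if self.order == AROMATIC else float(self.order)


@dataclass
class MolecularGraph:
    atoms: list[Atom] = field(default_factory=list)
    bonds: list[Bond] = field(default_factory=list)
    name: str = ""

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        seen_idx = set()
        for pos, atom in enumerate(self.atoms):
            if atom.index != pos:
                raise ValidationError(
                    f"atom at position {pos} carries index {atom.index}"
                )
            seen_idx.add(atom.index)
        pairs = set()
        for bond in self.bonds:
            if bond.a not in seen_idx or bond.b not in seen_idx:
                raise ValidationError(
                    f"bond {bond.a}-{bond.b} references a missing atom"
                )
            if bond.pair in pairs:
                raise ValidationError(f"duplicate bond between {bond.a} and {bond.b}")
            pairs.add(bond.pair)

    # -- structural helpers -------------------------------------------------

    def neighbors(self, i: int) -> list[tuple[int, Bond]]:
        out = []
        for bond in self.bonds:
            if bond.a == i:
                out.append((bond.b, bond))
            elif bond.b == i:
                out.append((bond.a, bond))
        return out

    def degree(self, i: int) -> int:
        return len(self.neighbors(i))

    def permuted(self, order: list[int]) -> "MolecularGraph":
        """Return a copy with atoms renumbered so old index ``order[k]``
        becomes new index ``k`` (``order`` is a permutation of indices)."""
        if sorted(order) != list(range(len(self.atoms))):
            raise ValidationError("order is not a permutation of atom indices")
        new_of_old = {old: new for new, old in enumerate(order)}
        atoms = [
            replace(self.atoms[old], index=new) for new, old in enumerate(order)
        ]
        bonds = [
            Bond(new_of_old[b.a], new_of_old[b.b], b.order, b.stereo)
            for b in self.bonds
        ]
        return MolecularGraph(atoms, bonds, self.name)


# ---------------------------------------------------------------------------
# molfile V2000 parsing and writing
# ---------------------------------------------------------------------------


def parse_molfile(text: str) -> MolecularGraph:
    """Parse an MDL molfile (V2000 dialect) into a :class:`MolecularGraph`.

    The three header lines are skipped (line 1 becomes the graph name);
    old-style charge columns are honoured unless any ``M  CHG`` line is
    present, in which case those supersede the whole column, as the
    format prescribes.  V3000 input is rejected.
    """
    lines = text.splitlines()
    if len(lines) < 4:
        raise MolfileError("molfile has no counts line (needs >= 4 lines)")
    name = lines[0].strip()
    counts = lines[3]
    if "V3000" in counts:
        raise MolfileError("V3000 connection tables are not supported; "
                           "supply V2000", line=4)
    if "V2000" not in counts:
        raise MolfileError("counts line lacks a V2000 version tag", line=4)
    try:
        n_atoms = int(counts[0:3])
        n_bonds = int(counts[3:6])
    except (ValueError, IndexError):
        raise MolfileError("malformed counts line", line=4) from None
    if n_atoms < 0 or n_bonds < 0:
        raise MolfileError("negative counts", line=4)

    atom_start = 4
    bond_start = atom_start + n_atoms
    body = lines[atom_start:]

    atoms: list[Atom] = []
    column_charges: dict[int, int] = {}
    for k in range(n_atoms):
        lineno = atom_start + k + 1
        if k >= len(body) or _is_terminator(body[k]):
            raise MolfileError(
                f"counts line declares {n_atoms} atoms but the atom block "
                f"ends after {k}", line=lineno)
        line = body[k]
        if len(line) >= 34:
            symbol = line[31:34].strip()
        else:
            parts = line.split()
            if len(parts) < 4:
                raise MolfileError("atom line too short", line=lineno)
            symbol = parts[3]
        if not symbol:
            raise MolfileError("empty element symbol", line=lineno)
        if symbol not in periodic.KNOWN_ELEMENTS:
            raise MolfileError(f"unknown element symbol {symbol!r}", line=lineno)
        if len(line) >= 39:
            try:
                code = int(line[36:39])
            except ValueError:
                code = 0
            charge = _CHG_COLUMN.get(code, 0)
            if charge:
                column_charges[k] = charge
        atoms.append(Atom(index=k, element=symbol))

    bonds: list[Bond] = []
    aromatic_atoms: set[int] = set()
    for k in range(n_bonds):
        lineno = bond_start + k + 1
        row = n_atoms + k
        if row >= len(body) or _is_terminator(body[row]):
            raise MolfileError(
                f"counts line declares {n_bonds} bonds but the bond block "
                f"ends after {k}", line=lineno)
        line = body[row]
        try:
            a = int(line[0:3]) - 1
            b = int(line[3:6]) - 1
            code = int(line[6:9])
        except (ValueError, IndexError):
            raise MolfileError("malformed bond line", line=lineno) from None
        stereo = 0
        if len(line) >= 12 and line[9:12].strip():
            try:
                stereo = int(line[9:12])
            except ValueError:
                stereo = 0
        if not (0 <= a < n_atoms) or not (0 <= b < n_atoms):
            raise MolfileError(
                f"bond references atom {max(a, b) + 1} outside the atom block",
                line=lineno)
        if code == 4:
            order: int | str = AROMATIC
            aromatic_atoms.update((a, b))
        elif code in (1, 2, 3):
            order = code
        else:
            raise MolfileError(f"unsupported bond type {code}", line=lineno)
        try:
            bonds.append(Bond(a, b, order, stereo))
        except ValidationError as exc:
            raise MolfileError(str(exc), line=lineno) from None

    chg_lines = [ln for ln in body[n_atoms + n_bonds:] if ln.startswith("M  CHG")]
    if chg_lines:
        column_charges = {}
        for ln in chg_lines:
            fields = ln.split()
            try:
                count = int(fields[2])
                pairs = fields[3:3 + 2 * count]
                for i in range(count):
                    idx = int(pairs[2 * i]) - 1
                    val = int(pairs[2 * i + 1])
                    if not (0 <= idx < n_atoms):
                        raise MolfileError(
                            f"M CHG references atom {idx + 1} outside the block")
                    column_charges[idx] = val
            except (IndexError, ValueError):
                raise MolfileError(f"malformed charge line {ln!r}") from None
    for idx, charge in column_charges.items():
        atoms[idx].formal_charge = charge
    for idx in aromatic_atoms:
        atoms[idx].aromatic = True

    graph = MolecularGraph(atoms, bonds, name)
    duplicates = len(bonds) - len({b.pair for b in bonds})
    if duplicates:
        raise MolfileError("duplicate bond in bond block")
    return graph


def _is_terminator(line: str) -> bool:
    return line.startswith("M  END") or line.startswith("$$$$")


def write_molfile(g: MolecularGraph) -> str:
    """Serialise a graph as an MDL V2000 molfile.

    Coordinates are zeroed (2D layout is out of scope); charges are
    emitted as ``M  CHG`` lines; wedge/hash codes ride along verbatim.
    """
    if len(g.atoms) > 999 or len(g.bonds) > 999:
        raise CapacityError("V2000 connection tables hold at most 999 atoms/bonds")
    out = [g.name, "  elnkit            2D", ""]
    out.append(f"{len(g.atoms):3d}{len(g.bonds):3d}  0  0  0  0  0  0  0  0999 V2000")
    for atom in g.atoms:
        out.append(
            f"{0.0:10.4f}{0.0:10.4f}{0.0:10.4f} {atom.element:<3s} 0  0  0  0  0"
            "  0  0  0  0  0  0  0"
        )
    for bond in g.bonds:
        code = 4 if bond.order == AROMATIC else bond.order
        out.append(f"{bond.a + 1:3d}{bond.b + 1:3d}{code:3d}{bond.stereo:3d}")
    charged = [(a.index + 1, a.formal_charge) for a in g.atoms if a.formal_charge]
    for start in range(0, len(charged), 8):
        chunk = charged[start:start + 8]
        out.append("M  CHG" + f"{len(chunk):3d}"
                   + "".join(f"{i:4d}{v:4d}" for i, v in chunk))
    out.append("M  END")
    return "\n".join(out) + "\n"


# ---------------------------------------------------------------------------
# implicit hydrogens, formula, masses
# ---------------------------------------------------------------------------


def implicit_h(g: MolecularGraph, atom_index: int) -> int:
    """Implicit hydrogens on an atom under MDL default valences.

    Aromatic bonds count 1.5 toward the bond-order sum and the sum is
    floored; the magnitude of the formal charge and any explicit-H
    assertion are subtracted.  Hydrogen atoms themselves never gain
    implicit hydrogens.  Floor is 0.
    """
    atom = g.atoms[atom_index]
    if atom.element == "H":
        return 0
    valence = periodic.default_valence(atom.element)
    order_sum = int(sum(b.numeric_order() for _, b in g.neighbors(atom_index)))
    free = valence - order_sum - abs(atom.formal_charge) - atom.explicit_h
    return max(0, free)


def _h_count(g: MolecularGraph) -> int:
    return sum(implicit_h(g, a.index) + a.explicit_h for a in g.atoms)


def molecular_formula(g: MolecularGraph) -> str:
    """Hill-order molecular formula (C, H, then alphabetical), counting
    implicit hydrogens."""
    counts: dict[str, int] = {}
    for atom in g.atoms:
        counts[atom.element] = counts.get(atom.element, 0) + 1
    h_total = counts.pop("H", 0) + _h_count(g)
    parts: list[str] = []
    if "C" in counts:
        parts.append(_term("C", counts.pop("C")))
        if h_total:
            parts.append(_term("H", h_total))
            h_total = 0
    if h_total:
        counts["H"] = counts.get("H", 0) + h_total
    for el in sorted(counts):
        parts.append(_term(el, counts[el]))
    return "".join(parts)


def _term(el: str, n: int) -> str:
    return el if n == 1 else f"{el}{n}"


def average_mass(g: MolecularGraph) -> float:
    """Molecular (average) mass in g/mol, to 4 decimals."""
    total = sum(periodic.atomic_weight(a.element) for a in g.atoms)
    total += _h_count(g) * periodic.atomic_weight("H")
    return round(total, 4)


def monoisotopic_mass(g: MolecularGraph) -> float:
    """Exact (monoisotopic) mass in Da, to 4 decimals."""
    total = sum(periodic.monoisotopic_mass(a.element) for a in g.atoms)
    total += _h_count(g) * periodic.monoisotopic_mass("H")
    return round(total, 4)


# ---------------------------------------------------------------------------
# structure keys
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StructureKey:
    """Deduplication key for a molecular graph.

    ``kind`` records which backend produced the value: ``"inchikey"``
    for the delegated toolkit, ``"fallback"`` for the built-in canonical
    key.  Keys of different kinds are never comparable.
    """

    kind: str
    value: str

    def __post_init__(self):
        if not self.value:
            raise ValidationError("structure key value must be non-empty")


def structure_key(g: MolecularGraph, backend: str = "toolkit") -> StructureKey:
    """Compute the permutation-invariant key used for deduplication."""
    if backend == "toolkit":
        return StructureKey("inchikey", _toolkit_inchikey(g))
    if backend == "fallback":
        digest = hashlib.sha256(canonical_signature(g).encode()).hexdigest()
        return StructureKey("fallback", digest[:32].upper())
    raise ValidationError(f"unknown structure-key backend {backend!r}")


def _toolkit_inchikey(g: MolecularGraph) -> str:
    try:
        from rdkit import Chem, RDLogger
    except ImportError:  # pragma: no cover
        raise BackendError(
            "RDKit is not importable; use structure_key(g, backend='fallback')"
        ) from None
    RDLogger.DisableLog("rdApp.*")
    mol = Chem.MolFromMolBlock(write_molfile(g), sanitize=True)
    if mol is None:
        raise BackendError("toolkit could not sanitise the structure")
    key = Chem.inchi.MolToInchiKey(mol)
    if not key:
        raise BackendError("toolkit returned no InChIKey")
    return key


def _initial_colors(g: MolecularGraph) -> list[tuple]:
    return [
        (a.element, a.formal_charge, a.aromatic, g.degree(a.index), a.explicit_h)
        for a in g.atoms
    ]


def _bond_token(b: Bond) -> str:
    return "a" if b.order == AROMATIC else str(b.order)


def _refine(g: MolecularGraph, colors: list[int]) -> list[int]:
    """Morgan-style refinement: iterate neighbourhood hashing to a fixed
    partition.  Ranks are assigned from sorted invariant tuples, so the
    result is independent of input atom order."""
    n = len(g.atoms)
    while True:
        raw = []
        for i in range(n):
            env = sorted((_bond_token(b), colors[j]) for j, b in g.neighbors(i))
            raw.append((colors[i], tuple(env)))
        ranks = {v: r for r, v in enumerate(sorted(set(raw)))}
        new = [ranks[v] for v in raw]
        if len(set(new)) == len(set(colors)):
            return new
        colors = new


def canonical_signature(g: MolecularGraph) -> str:
    """Canonical adjacency string: identical for isomorphic graphs,
    distinct signatures imply non-isomorphic graphs.

    Colour refinement is followed, where classes remain ambiguous, by
    individualisation-refinement: each member of the first ambiguous
    class is tried in turn and the lexicographically smallest resulting
    string wins.  Exponential only on highly symmetric graphs, which at
    notebook molecule sizes is immaterial.
    """
    init = _initial_colors(g)
    ranks = {v: r for r, v in enumerate(sorted(set(init)))}
    return _canon(g, _refine(g, [ranks[v] for v in init]))


def _canon(g: MolecularGraph, colors: list[int]) -> str:
    n = len(g.atoms)
    if len(set(colors)) == n:
        return _signature_string(g, colors)
    # first ambiguous class by colour value
    by_color: dict[int, list[int]] = {}
    for i, c in enumerate(colors):
        by_color.setdefault(c, []).append(i)
    target = min(c for c, members in by_color.items() if len(members) > 1)
    best: str | None = None
    for pick in by_color[target]:
        # individualise: give the picked atom a colour strictly between its
        # class and the one below, without touching any other class
        branched = [2 * c - (1 if i == pick else 0) for i, c in enumerate(colors)]
        ranks = {v: r for r, v in enumerate(sorted(set(branched)))}
        sig = _canon(g, _refine(g, [ranks[v] for v in branched]))
        if best is None or sig < best:
            best = sig
    assert best is not None
    return best


def _signature_string(g: MolecularGraph, colors: list[int]) -> str:
    pos = {i: c for i, c in enumerate(colors)}
    atoms = sorted(g.atoms, key=lambda a: pos[a.index])
    atom_part = ";".join(
        f"{a.element},{a.formal_charge},{int(a.aromatic)},{a.explicit_h}"
        for a in atoms
    )
    bond_part = ";".join(
        f"{x}-{y}:{t}"
        for x, y, t in sorted(
            (min(pos[b.a], pos[b.b]), max(pos[b.a], pos[b.b]), _bond_token(b))
            for b in g.bonds
        )
    )
    return atom_part + "|" + bond_part


# ---------------------------------------------------------------------------
# SMILES convenience input (delegated)
# ---------------------------------------------------------------------------


def graph_from_smiles(smiles: str, name: str = "", kekulize: bool = True
                      ) -> MolecularGraph:
    """Build a graph from a SMILES string via the delegated toolkit.

    With ``kekulize=False`` aromatic rings come through as aromatic
    (type 4) bonds and flagged atoms; otherwise alternating single and
    double bonds are written, matching how most editors save molfiles.
    """
    try:
        from rdkit import Chem, RDLogger
    except ImportError:  # pragma: no cover
        raise BackendError("RDKit is required for SMILES input") from None
    RDLogger.DisableLog("rdApp.*")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValidationError(f"unparseable SMILES {smiles!r}")
    block = Chem.MolToMolBlock(mol, kekulize=kekulize)
    g = parse_molfile(block)
    g.name = name or smiles
    return g


def canonical_smiles(g: MolecularGraph) -> str | None:
    """Delegated canonical SMILES, or None when no toolkit is available."""
    try:
        from rdkit import Chem, RDLogger
    except ImportError:  # pragma: no cover
        return None
    RDLogger.DisableLog("rdApp.*")
    mol = Chem.MolFromMolBlock(write_molfile(g), sanitize=True)
    if mol is None:
        return None
    return Chem.MolToSmiles(mol)


def inchi_string(g: MolecularGraph) -> str | None:
    """Delegated InChI, or None when no toolkit is available."""
    try:
        from rdkit import Chem, RDLogger
    except ImportError:  # pragma: no cover
        return None
    RDLogger.DisableLog("rdApp.*")
    mol = Chem.MolFromMolBlock(write_molfile(g), sanitize=True)
    if mol is None:
        return None
    return Chem.MolToInchi(mol)
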