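"""Deterministic synthetic molecular fixtures.

The generator grows random connected molecular graphs (a spanning tree
plus optional ring closures) over a small organic element palette,
respecting MDL default valences, so every generated structure parses,
registers and fingerprints like a drawn one.  A stated fraction of the
output are atom-permuted duplicates of earlier structures, which is
exactly what a registry's deduplication has to absorb.  A curated set
of ~30 named common molecules (as SMILES, converted through the
toolkit) complements the random graphs for tests that need recognisable
chemistry.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

from . import periodic
from .chemgraph import Atom, Bond, MolecularGraph, graph_from_smiles
from .errors import ValidationError

DEFAULT_PALETTE = ("C", "N", "O", "S", "F", "Cl", "Br")
# heavier weight on carbon mirrors organic-chemistry composition
_PALETTE_WEIGHTS = {"C": 10, "N": 2, "O": 3, "S": 1, "F": 1, "Cl": 1, "Br": 1}


@dataclass(frozen=True)
class FixtureSpec:
    seed: int = 42
    n_molecules: int = 20
    max_heavy_atoms: int = 12
    element_palette: tuple[str, ...] = DEFAULT_PALETTE
    ring_probability: float = 0.3
    duplicate_rate: float = 0.2
    multiple_bond_probability: float = 0.25

    def __post_init__(self):
        if self.n_molecules < 1:
            raise ValidationError("n_molecules must be >= 1")
        if not (2 <= self.max_heavy_atoms <= 16):
            raise ValidationError("max_heavy_atoms must lie in 2..16")
        if not self.element_palette:
            raise ValidationError("element palette must not be empty")
        for el in self.element_palette:
            if periodic.default_valence(el) < 1:
                raise ValidationError(
                    f"{el} has no default valence; it cannot bond")
        if not (0.0 <= self.ring_probability <= 1.0):
            raise ValidationError("ring_probability must lie in [0, 1]")
        if not (0.0 <= self.duplicate_rate <= 1.0):
            raise ValidationError("duplicate_rate must lie in [0, 1]")


def _pick_element(rng: random.Random, palette: tuple[str, ...]) -> str:
    weights = [_PALETTE_WEIGHTS.get(el, 1) for el in palette]
    return rng.choices(palette, weights=weights, k=1)[0]


def random_graph(rng: random.Random, spec: FixtureSpec,
                 name: str = "") -> MolecularGraph:
    """One random connected, valence-legal molecular graph."""
    n = rng.randint(2, spec.max_heavy_atoms)
    elements = [_pick_element(rng, spec.element_palette) for _ in range(n)]
    free = [periodic.default_valence(el) for el in elements]
    atoms = [Atom(i, el) for i, el in enumerate(elements)]
    bonds: list[Bond] = []
    bonded: set[tuple[int, int]] = set()

    for i in range(1, n):
        anchors = [j for j in range(i) if free[j] >= 1]
        if not anchors:
            # all earlier atoms saturated (e.g. run of halogens): leave
            # the rest as a disconnected fragment of one atom each
            continue
        j = rng.choice(anchors)
        order = 1
        if free[i] >= 2 and free[j] >= 2 \
                and rng.random() < spec.multiple_bond_probability:
            order = 2
            if free[i] >= 3 and free[j] >= 3 and rng.random() < 0.3:
                order = 3
        bonds.append(Bond(j, i, order))
        bonded.add((j, i))
        free[i] -= order
        free[j] -= order

    if rng.random() < spec.ring_probability:
        open_atoms = [i for i in range(n) if free[i] >= 1]
        rng.shuffle(open_atoms)
        for a in open_atoms:
            partners = [b for b in open_atoms
                        if b > a and (a, b) not in bonded and free[b] >= 1]
            if partners:
                b = rng.choice(partners)
                bonds.append(Bond(a, b, 1))
                free[a] -= 1
                free[b] -= 1
                break
    return MolecularGraph(atoms, bonds, name)


def generate_fixtures(spec: FixtureSpec) -> list[MolecularGraph]:
    """Deterministic fixture set; ``duplicate_rate`` of the output are
    atom-permuted copies of earlier members."""
    rng = random.Random(spec.seed)
    graphs: list[MolecularGraph] = []
    for i in range(spec.n_molecules):
        if graphs and rng.random() < spec.duplicate_rate:
            source = rng.choice(graphs)
            order = list(range(len(source.atoms)))
            rng.shuffle(order)
            dup = source.permuted(order)
            dup.name = f"FIX-{i}"
            graphs.append(dup)
        else:
            graphs.append(random_graph(rng, spec, name=f"FIX-{i}"))
    return graphs


# ---------------------------------------------------------------------------
# curated named molecules
# ---------------------------------------------------------------------------

#: ~30 common molecules; aromatics marked so rings come through flagged
CURATED_SMILES: dict[str, str] = {
    "water": "O",
    "methane": "C",
    "methanol": "CO",
    "ethanol": "CCO",
    "dimethyl ether": "COC",
    "1-propanol": "CCCO",
    "2-propanol": "CC(O)C",
    "acetic acid": "CC(=O)O",
    "formaldehyde": "C=O",
    "acetone": "CC(=O)C",
    "acetonitrile": "CC#N",
    "urea": "NC(=O)N",
    "glycerol": "OCC(O)CO",
    "diethyl ether": "CCOCC",
    "ethyl acetate": "CCOC(=O)C",
    "tetrahydrofuran": "C1CCOC1",
    "1,4-dioxane": "C1COCCO1",
    "dichloromethane": "ClCCl",
    "chloroform": "ClC(Cl)Cl",
    "dimethylformamide": "CN(C)C=O",
    "dimethyl sulfoxide": "CS(=O)C",
    "hexane": "CCCCCC",
    "cyclohexane": "C1CCCCC1",
    "cyclohexanol": "OC1CCCCC1",
    "benzene": "c1ccccc1",
    "toluene": "Cc1ccccc1",
    "phenol": "Oc1ccccc1",
    "aniline": "Nc1ccccc1",
    "pyridine": "c1ccncc1",
    "benzaldehyde": "O=Cc1ccccc1",
    "styrene": "C=Cc1ccccc1",
    "naphthalene": "c1ccc2ccccc2c1",
    "aspirin": "CC(=O)Oc1ccccc1C(=O)O",
}


def curated_graphs(aromatic: bool = True) -> dict[str, MolecularGraph]:
    """The curated molecules as parsed graphs (via the toolkit).

    With ``aromatic=True`` aromatic rings carry type-4 bonds and flags;
    otherwise Kekulé structures are produced.
    """
    return {
        name: graph_from_smiles(smiles, name=name, kekulize=not aromatic)
        for name, smiles in CURATED_SMILES.items()
    }
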