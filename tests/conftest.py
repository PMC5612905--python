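import pytest

from elnkit.chemgraph import Atom, Bond, MolecularGraph
from elnkit.store import Store


def make_graph(elements, bonds, name=""):
    """Compact graph builder: elements like ["C", ("O", -1)], bonds like
    [(0, 1), (1, 2, 2)] (third member = order)."""
    atoms = []
    for i, spec in enumerate(elements):
        if isinstance(spec, tuple):
            el, charge = spec
            atoms.append(Atom(i, el, formal_charge=charge))
        else:
            atoms.append(Atom(i, spec))
    bond_objs = [Bond(b[0], b[1], b[2] if len(b) > 2 else 1) for b in bonds]
    return MolecularGraph(atoms, bond_objs, name)


@pytest.fixture
def store():
    s = Store()
    yield s
    s.close()


@pytest.fixture
def ethanol():
    return make_graph(["C", "C", "O"], [(0, 1), (1, 2)], "ethanol")


@pytest.fixture
def water():
    return make_graph(["O"], [], "water")


@pytest.fixture
def propanol():
    return make_graph(["C", "C", "C", "O"], [(0, 1), (1, 2), (2, 3)],
                      "1-propanol")
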