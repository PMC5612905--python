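"""Text and structure search.

Text search uses trigram similarity with pg_trgm semantics: words are
lower-cased, split on non-alphanumerics, padded with two leading and
one trailing space, and compared by Jaccard overlap of their 3-grams.

Structure search is fingerprint-based.  The fingerprint hashes every
canonical linear path of 2–7 atoms (atom element + aromatic flag,
alternating with bond orders) into a fixed-width bitset via FNV-1a;
similarity is the Tanimoto coefficient over set bits.  Substructure
search screens candidates by bit containment, then verifies hits
exactly with VF2 subgraph monomorphism, so reported matches are never
false positives.  Bit-compatibility with any external toolkit's
fingerprints is not claimed; determinism across runs and platforms is.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass

import networkx as nx

from .chemgraph import AROMATIC, MolecularGraph, parse_molfile
from .errors import ValidationError
from .store import Store

DEFAULT_NBITS = 1024
PATH_MIN = 2
PATH_MAX = 7
TEXT_THRESHOLD = 0.3
SIMILARITY_THRESHOLD = 0.7

# alphanumeric words, Unicode-aware (underscore is a separator)
_WORD_RE = re.compile(r"[^\W_]+")


# ---------------------------------------------------------------------------
# trigram text similarity
# ---------------------------------------------------------------------------


def trigram_set(text: str) -> frozenset[str]:
    """All 3-grams of the padded, lower-cased words of ``text``."""
    grams: set[str] = set()
    for word in _WORD_RE.findall(text.lower()):
        padded = "  " + word + " "
        grams.update(padded[i:i + 3] for i in range(len(padded) - 2))
    return frozenset(grams)


def trigram_similarity(a: str, b: str) -> float:
    """Jaccard overlap of the two trigram sets; 0.0 when both are empty."""
    ga, gb = trigram_set(a), trigram_set(b)
    union = ga | gb
    if not union:
        return 0.0
    return len(ga & gb) / len(union)


_SEARCHED_FIELDS = ("label", "iupac_name", "sum_formula", "inchi_string",
                    "canonical_smiles", "external_label")


def text_search(query: str, store: Store, element_filter: str = "all",
                threshold: float = TEXT_THRESHOLD) -> dict[str, list]:
    """Rank samples by the best trigram similarity over their searched
    fields (name, formula, IUPAC name, InChI, canonical SMILES);
    reactions are included when any of their samples hit.

    Returns ``{"samples": [(sample_id, score)...], "reactions": [ids]}``
    restricted by ``element_filter`` in {"all", "samples", "reactions"}.
    """
    if not query:
        raise ValidationError("empty search query")
    if element_filter not in ("all", "samples", "reactions"):
        raise ValidationError("element_filter is all, samples or reactions")
    scored: list[tuple[int, float]] = []
    for row in store.query(
            "SELECT s.id, s.label, s.external_label, m.iupac_name,"
            " m.sum_formula, m.inchi_string, m.canonical_smiles"
            " FROM samples s JOIN molecules m ON m.id = s.molecule_id"
            " ORDER BY s.id"):
        best = max(trigram_similarity(query, row[f] or "")
                   for f in _SEARCHED_FIELDS)
        if best >= threshold:
            scored.append((row["id"], best))
    scored.sort(key=lambda t: (-t[1], t[0]))
    hit_ids = {sid for sid, _ in scored}
    reactions: list[int] = []
    if hit_ids:
        placeholders = ",".join("?" * len(hit_ids))
        reactions = [r["reaction_id"] for r in store.query(
            f"SELECT DISTINCT reaction_id FROM participants"
            f" WHERE sample_id IN ({placeholders}) ORDER BY reaction_id",
            tuple(hit_ids))]
    out = {"samples": scored, "reactions": reactions}
    if element_filter == "samples":
        out["reactions"] = []
    elif element_filter == "reactions":
        out["samples"] = []
    return out


# ---------------------------------------------------------------------------
# path fragments and fingerprints
# ---------------------------------------------------------------------------


def _atom_token(g: MolecularGraph, i: int) -> str:
    a = g.atoms[i]
    return a.element + ("*" if a.aromatic else "")


def _bond_token(order) -> str:
    return "a" if order == AROMATIC else str(order)


def path_fragments(g: MolecularGraph,
                   max_atoms: int = PATH_MAX) -> Counter[str]:
    """Multiset of canonical linear-fragment strings.

    Every simple (non-revisiting) path of 2..``max_atoms`` atoms is
    encoded as alternating atom and bond tokens; the canonical form is
    the lexicographically smaller of the two traversal directions.
    Each undirected path contributes once.
    """
    counts: Counter[str] = Counter()

    def extend(path: list[int], tokens: list[str]) -> None:
        last = path[-1]
        for nbr, bond in g.neighbors(last):
            if nbr in path:
                continue
            toks = tokens + [_bond_token(bond.order), _atom_token(g, nbr)]
            new_path = path + [nbr]
            if len(new_path) >= PATH_MIN:
                counts[min("".join(toks), "".join(reversed(toks)))] += 1
            if len(new_path) < max_atoms:
                extend(new_path, toks)

    for start in range(len(g.atoms)):
        extend([start], [_atom_token(g, start)])
    # each path was found from both of its ends
    for key in counts:
        counts[key] //= 2
    return counts


def _fnv1a(data: bytes) -> int:
    h = 0x811C9DC5
    for byte in data:
        h ^= byte
        h = (h * 0x01000193) & 0xFFFFFFFF
    return h


@dataclass(frozen=True)
class Fingerprint:
    """Fixed-width path fingerprint; ``bits`` is an int bitmask."""

    bits: int
    nbits: int = DEFAULT_NBITS
    path_max: int = PATH_MAX

    def popcount(self) -> int:
        return self.bits.bit_count()

    def contains(self, other: "Fingerprint") -> bool:
        """True when every set bit of ``other`` is set here (screen)."""
        self._check(other)
        return other.bits & self.bits == other.bits

    def _check(self, other: "Fingerprint") -> None:
        if self.nbits != other.nbits:
            raise ValidationError(
                f"fingerprint widths differ: {self.nbits} vs {other.nbits}")


def fingerprint(g: MolecularGraph, nbits: int = DEFAULT_NBITS,
                path_max: int = PATH_MAX) -> Fingerprint:
    """Hash each distinct fragment with FNV-1a mod ``nbits``; set that bit."""
    bits = 0
    for frag in path_fragments(g, max_atoms=path_max):
        bits |= 1 << (_fnv1a(frag.encode()) % nbits)
    return Fingerprint(bits=bits, nbits=nbits, path_max=path_max)


def tanimoto(fa: Fingerprint, fb: Fingerprint) -> float:
    """|A∩B| / |A∪B| over set bits.  Two empty fingerprints (no paths —
    e.g. single-atom graphs) compare as identical: 1.0."""
    fa._check(fb)
    union = (fa.bits | fb.bits).bit_count()
    if union == 0:
        return 1.0
    return (fa.bits & fb.bits).bit_count() / union


# ---------------------------------------------------------------------------
# store-backed structure search
# ---------------------------------------------------------------------------


def _molecule_graphs(store: Store):
    for row in store.query("SELECT id, molfile FROM molecules ORDER BY id"):
        yield row["id"], parse_molfile(row["molfile"])


def similarity_search(query_graph: MolecularGraph, store: Store,
                      threshold: float = SIMILARITY_THRESHOLD,
                      nbits: int = DEFAULT_NBITS
                      ) -> list[tuple[int, float]]:
    """Molecules with Tanimoto >= threshold, sorted descending; ties
    keep registration order."""
    if not (0.0 <= threshold <= 1.0):
        raise ValidationError("threshold must lie in [0, 1]")
    fq = fingerprint(query_graph, nbits=nbits)
    hits = []
    for mol_id, g in _molecule_graphs(store):
        score = tanimoto(fq, fingerprint(g, nbits=nbits))
        if score >= threshold:
            hits.append((mol_id, score))
    hits.sort(key=lambda t: (-t[1], t[0]))
    return hits


def _to_nx(g: MolecularGraph) -> nx.Graph:
    gx = nx.Graph()
    for a in g.atoms:
        gx.add_node(a.index, element=a.element, aromatic=a.aromatic)
    for b in g.bonds:
        gx.add_edge(b.a, b.b, order=_bond_token(b.order))
    return gx


def is_substructure(query: MolecularGraph, target: MolecularGraph) -> bool:
    """Exact subgraph-monomorphism check (VF2).

    Atoms match on element + aromatic flag; bonds on order, with
    aromatic distinct from single.  Extra bonds in the target between
    mapped atoms are allowed (monomorphism, the chemical convention).
    """
    node_match = nx.algorithms.isomorphism.categorical_node_match(
        ["element", "aromatic"], [None, None])
    edge_match = nx.algorithms.isomorphism.categorical_edge_match(
        "order", None)
    matcher = nx.algorithms.isomorphism.GraphMatcher(
        _to_nx(target), _to_nx(query),
        node_match=node_match, edge_match=edge_match)
    return matcher.subgraph_is_monomorphic()


def substructure_search(query_graph: MolecularGraph, store: Store,
                        nbits: int = DEFAULT_NBITS) -> list[int]:
    """Two-stage substructure search over registered molecules.

    Stage 1 screens by fingerprint containment (sound: a true match can
    never be screened out, because every query path maps to an identical
    path in the match).  Stage 2 verifies survivors by VF2.
    """
    fq = fingerprint(query_graph, nbits=nbits)
    hits = []
    for mol_id, g in _molecule_graphs(store):
        if not fingerprint(g, nbits=nbits).contains(fq):
            continue
        if is_substructure(query_graph, g):
            hits.append(mol_id)
    return hits


def screen_candidates(query_graph: MolecularGraph, store: Store,
                      nbits: int = DEFAULT_NBITS) -> list[int]:
    """Stage-1 survivors only (useful for measuring screen precision)."""
    fq = fingerprint(query_graph, nbits=nbits)
    return [mol_id for mol_id, g in _molecule_graphs(store)
            if fingerprint(g, nbits=nbits).contains(fq)]
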