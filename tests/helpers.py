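"""Independent oracles used by the test suite.

Everything here is deliberately coded from first principles — brute
force, exhaustive enumeration, plain set arithmetic — and shares no
code path with the implementation it checks.
"""

from __future__ import annotations

from itertools import permutations

from elnkit.chemgraph import AROMATIC, MolecularGraph


def _atom_sig(g: MolecularGraph, i: int) -> tuple:
    a = g.atoms[i]
    return (a.element, a.formal_charge, a.aromatic, a.explicit_h)


def _bond_map(g: MolecularGraph) -> dict[tuple[int, int], object]:
    return {b.pair: b.order for b in g.bonds}


def graphs_isomorphic(g1: MolecularGraph, g2: MolecularGraph) -> bool:
    """Brute-force labelled-graph isomorphism by permutation search with
    simple pruning (practical for the <= 12 heavy atoms used in tests)."""
    n = len(g1.atoms)
    if n != len(g2.atoms) or len(g1.bonds) != len(g2.bonds):
        return False
    if sorted(_atom_sig(g1, i) for i in range(n)) \
            != sorted(_atom_sig(g2, i) for i in range(n)):
        return False
    b1, b2 = _bond_map(g1), _bond_map(g2)
    adj1: dict[int, dict[int, object]] = {i: {} for i in range(n)}
    for (a, b), order in b1.items():
        adj1[a][b] = order
        adj1[b][a] = order
    adj2: dict[int, dict[int, object]] = {i: {} for i in range(n)}
    for (a, b), order in b2.items():
        adj2[a][b] = order
        adj2[b][a] = order

    # candidate targets per g1 atom: same signature and degree
    candidates = [
        [j for j in range(n)
         if _atom_sig(g1, i) == _atom_sig(g2, j)
         and len(adj1[i]) == len(adj2[j])]
        for i in range(n)
    ]

    mapping: dict[int, int] = {}
    used: set[int] = set()

    def extend(i: int) -> bool:
        if i == n:
            return True
        for j in candidates[i]:
            if j in used:
                continue
            ok = True
            for k, order in adj1[i].items():
                if k < i and adj2[j].get(mapping[k]) != order:
                    ok = False
                    break
            # also no extra bonds from j to already-mapped atoms
            if ok:
                mapped = {mapping[k] for k in range(i)}
                extra = sum(1 for t in adj2[j] if t in mapped)
                expect = sum(1 for k in adj1[i] if k < i)
                ok = extra == expect
            if ok:
                mapping[i] = j
                used.add(j)
                if extend(i + 1):
                    return True
                used.discard(j)
                del mapping[i]
        return False

    return extend(0)


def count_distinct_structures(graphs: list[MolecularGraph]) -> int:
    """Ground-truth distinct-structure count by pairwise isomorphism."""
    representatives: list[MolecularGraph] = []
    for g in graphs:
        if not any(graphs_isomorphic(g, rep) for rep in representatives):
            representatives.append(g)
    return len(representatives)


def subgraph_monomorphic(query: MolecularGraph,
                         target: MolecularGraph) -> bool:
    """Brute-force injective-mapping subgraph search.  Every query atom
    maps to a distinct target atom of equal signature; every query bond
    maps to a target bond of equal order.  Extra target bonds between
    mapped atoms are permitted."""
    nq, nt = len(query.atoms), len(target.atoms)
    if nq > nt:
        return False
    adj_q: dict[int, dict[int, object]] = {i: {} for i in range(nq)}
    for b in query.bonds:
        adj_q[b.a][b.b] = b.order
        adj_q[b.b][b.a] = b.order
    adj_t: dict[int, dict[int, object]] = {i: {} for i in range(nt)}
    for b in target.bonds:
        adj_t[b.a][b.b] = b.order
        adj_t[b.b][b.a] = b.order

    mapping: dict[int, int] = {}
    used: set[int] = set()

    def extend(i: int) -> bool:
        if i == nq:
            return True
        for j in range(nt):
            if j in used or _atom_sig(query, i) != _atom_sig(target, j):
                continue
            if len(adj_q[i]) > len(adj_t[j]):
                continue
            if any(k < i and adj_t[j].get(mapping[k]) != order
                   for k, order in adj_q[i].items()):
                continue
            mapping[i] = j
            used.add(j)
            if extend(i + 1):
                return True
            used.discard(j)
            del mapping[i]
        return False

    return extend(0)


def enumerate_paths(g: MolecularGraph, min_atoms: int = 2,
                    max_atoms: int = 7) -> set[str]:
    """Independent DFS path enumerator for fragment-set comparison."""
    frags: set[str] = set()

    def token(i: int) -> str:
        a = g.atoms[i]
        return a.element + ("*" if a.aromatic else "")

    def bond_tok(order) -> str:
        return "a" if order == AROMATIC else str(order)

    def walk(path: list[int], toks: list[str]) -> None:
        if min_atoms <= len(path):
            joined = "".join(toks)
            frags.add(min(joined, "".join(reversed(toks))))
        if len(path) == max_atoms:
            return
        for b in g.bonds:
            for nxt, other in ((b.b, b.a), (b.a, b.b)):
                if other == path[-1] and nxt not in path:
                    walk(path + [nxt], toks + [bond_tok(b.order), token(nxt)])

    for start in range(len(g.atoms)):
        walk([start], [token(start)])
    return frags


def trigram_similarity_oracle(a: str, b: str) -> float:
    """pg_trgm-style similarity via plain set arithmetic (independent of
    the implementation's regex tokenizer)."""

    def grams(text: str) -> set[str]:
        out: set[str] = set()
        word = ""
        for ch in text.lower() + "\x00":
            if ch.isalnum():
                word += ch
            else:
                if word:
                    padded = "  " + word + " "
                    for i in range(len(padded) - 2):
                        out.add(padded[i:i + 3])
                word = ""
        return out

    ga, gb = grams(a), grams(b)
    if not ga and not gb:
        return 0.0
    return len(ga & gb) / len(ga | gb)
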