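"""Tree-topology catalog: canonical forms, enumeration, and RAG-style IDs.

The RAG naming scheme identifies each tree topology on n vertices as
``n_k``, where the rank k orders the non-isomorphic n-vertex trees by
increasing algebraic connectivity lambda2 — i.e. by topological
complexity, from the path (``n_1``) to the star (most compact).
Canonical forms use the AHU rooted-tree encoding anchored at the tree
centroid, so two graphs receive the same string exactly when they are
isomorphic; this is what makes "does this fragment correspond to a known
topology" a dictionary lookup.
"""

from __future__ import annotations

from collections.abc import Iterable, Sequence
from dataclasses import dataclass
from functools import lru_cache

from .errors import CatalogRangeError
from .graph import RAGTreeGraph, build_graph, spectrum

__all__ = [
    "CatalogEntry",
    "Catalog",
    "canonical_form",
    "enumerate_trees",
    "assign_rag_ids",
    "build_catalog",
    "identify",
]

#: enumeration is supported through this vertex count (511 topologies at 12)
MAX_CATALOG_N = 12

_LAMBDA2_TIE_TOL = 1e-9


# -- canonical forms -----------------------------------------------------


def _centroids(g: RAGTreeGraph) -> list[int]:
    """The one or two centroid vertices (minimizing the largest subtree)."""
    if g.n == 1:
        return [g.vertices[0]]
    adj = g.adjacency_lists()
    degree = {v: len(nb) for v, nb in adj.items()}
    remaining = g.n
    layer = [v for v, d in degree.items() if d <= 1]
    alive = set(g.vertices)
    # iteratively strip leaves; the last one or two vertices are the centroids
    while remaining > 2:
        remaining -= len(layer)
        nxt: list[int] = []
        for leaf in layer:
            alive.discard(leaf)
            for w in adj[leaf]:
                if w in alive:
                    degree[w] -= 1
                    if degree[w] == 1:
                        nxt.append(w)
        layer = nxt
    return sorted(alive)


def _ahu(root: int, parent: int | None, adj: dict[int, list[int]]) -> str:
    labels = sorted(
        _ahu(child, root, adj) for child in adj[root] if child != parent
    )
    return "(" + "".join(labels) + ")"


def canonical_form(g: RAGTreeGraph) -> str:
    """Label-invariant canonical string; equal iff the trees are isomorphic.

    AHU encoding rooted at the centroid; for bicentroidal trees the
    lexicographically smaller of the two rooted encodings is used.
    """
    adj = g.adjacency_lists()
    return min(_ahu(c, None, adj) for c in _centroids(g))


# -- enumeration ---------------------------------------------------------


def _leaf_extensions(g: RAGTreeGraph) -> Iterable[RAGTreeGraph]:
    n = g.n
    for v in g.vertices:
        edges = set(g.edges) | {(v, n + 1)}
        yield RAGTreeGraph(tuple(range(1, n + 2)), frozenset(edges))


@lru_cache(maxsize=None)
def _enumerate_cached(n: int) -> tuple[RAGTreeGraph, ...]:
    if n == 2:
        return (build_graph([(1, 2)], 2),)
    reps: dict[str, RAGTreeGraph] = {}
    for smaller in _enumerate_cached(n - 1):
        for candidate in _leaf_extensions(smaller):
            key = canonical_form(candidate)
            if key not in reps:
                reps[key] = candidate
    return tuple(reps[k] for k in sorted(reps))


def enumerate_trees(n: int) -> list[RAGTreeGraph]:
    """One representative per isomorphism class of n-vertex trees.

    Built by extending every (n-1)-vertex class with a new leaf at each
    vertex and deduplicating by canonical form (every n-vertex tree
    arises from deleting a leaf, so the sweep is exhaustive).
    Representatives are labeled 1..n.
    """
    if not (2 <= n <= MAX_CATALOG_N):
        raise CatalogRangeError(
            f"enumeration supports 2 <= n <= {MAX_CATALOG_N}, got {n}"
        )
    return list(_enumerate_cached(n))


# -- RAG identifiers -----------------------------------------------------


@dataclass(frozen=True)
class CatalogEntry:
    """A canonical tree topology with its lambda2-ordered identifier."""

    rag_id: str
    n: int
    k: int
    lambda2: float
    canonical: str
    edges: tuple[tuple[int, int], ...]

    def graph(self) -> RAGTreeGraph:
        return build_graph(self.edges, self.n, name=self.rag_id)


def assign_rag_ids(trees: Sequence[RAGTreeGraph]) -> list[CatalogEntry]:
    """Rank same-order trees by ascending lambda2 into ``n_k`` identifiers.

    Exact lambda2 ties between non-isomorphic trees (beyond 1e-9) are
    broken deterministically by the canonical string.
    """
    if not trees:
        return []
    sizes = {g.n for g in trees}
    if len(sizes) != 1:
        raise CatalogRangeError(f"trees of mixed order {sorted(sizes)}")
    n = sizes.pop()
    keyed = []
    for g in trees:
        keyed.append((spectrum(g).lambda2, canonical_form(g), g))
    # quantize lambda2 at the tie tolerance so the canonical string decides
    keyed.sort(key=lambda t: (round(t[0] / _LAMBDA2_TIE_TOL), t[1]))
    entries = []
    for k, (lam, canon, g) in enumerate(keyed, start=1):
        entries.append(
            CatalogEntry(
                rag_id=f"{n}_{k}",
                n=n,
                k=k,
                lambda2=lam,
                canonical=canon,
                edges=tuple(g.sorted_edges()),
            )
        )
    return entries


class Catalog:
    """Lambda2-ordered topology catalog over a range of vertex counts."""

    def __init__(self, entries: Iterable[CatalogEntry]):
        self.entries: list[CatalogEntry] = sorted(
            entries, key=lambda e: (e.n, e.k)
        )
        self._by_canonical = {(e.n, e.canonical): e for e in self.entries}
        self._orders = {e.n for e in self.entries}

    def covers(self, n: int) -> bool:
        return n in self._orders

    def for_n(self, n: int) -> list[CatalogEntry]:
        return [e for e in self.entries if e.n == n]

    def lookup(self, g: RAGTreeGraph) -> CatalogEntry | None:
        if not self.covers(g.n):
            raise CatalogRangeError(
                f"catalog has no entries with {g.n} vertices"
            )
        return self._by_canonical.get((g.n, canonical_form(g)))

    def get(self, rag_id: str) -> CatalogEntry:
        for e in self.entries:
            if e.rag_id == rag_id:
                return e
        raise KeyError(rag_id)

    def to_tsv(self) -> str:
        lines = ["rag_id\tlambda2\tcanonical\tedges"]
        for e in self.entries:
            edges = ";".join(f"{u}-{v}" for u, v in e.edges)
            lines.append(f"{e.rag_id}\t{e.lambda2:.6f}\t{e.canonical}\t{edges}")
        return "\n".join(lines) + "\n"


def build_catalog(n_min: int = 2, n_max: int = 11) -> Catalog:
    """Enumerate and rank all tree topologies with n_min..n_max vertices."""
    entries: list[CatalogEntry] = []
    for n in range(n_min, n_max + 1):
        entries.extend(assign_rag_ids(enumerate_trees(n)))
    return Catalog(entries)


def identify(g: RAGTreeGraph, catalog: Catalog) -> str | None:
    """RAG ID of the catalog topology isomorphic to ``g``, or None."""
    entry = catalog.lookup(g)
    return entry.rag_id if entry is not None else None
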