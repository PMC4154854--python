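"""Tree-graph data model, Laplacian construction, and the Fiedler pair.

An RNA secondary structure, coarse-grained in the RNA-As-Graphs (RAG) tree
representation, is an unrooted labeled tree: helices are edges, and
single-stranded elements (hairpin loops, internal loops/bulges, junctions,
exterior strands) are vertices, numbered 5'->3'.  The graph Laplacian
``L = D - A`` (degree matrix minus adjacency matrix) of such a tree is
symmetric positive semidefinite with smallest eigenvalue 0; its second
eigenvalue lambda2 (the algebraic connectivity) measures topological
compactness, and the corresponding unit eigenvector mu2 (the Fiedler
vector) orders vertices for spectral bisection.
"""

from __future__ import annotations

from collections.abc import Iterable, Sequence
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import (
    CycleError,
    DisconnectedError,
    DuplicateEdgeError,
    GraphValidationError,
    LabelRangeError,
    SelfLoopError,
)

__all__ = [
    "RAGTreeGraph",
    "LaplacianSpectrum",
    "build_graph",
    "laplacian",
    "spectrum",
    "fiedler",
    "read_edge_list",
    "write_edge_list",
    "orient_sign",
]

#: below this magnitude an eigenvector component counts as zero when fixing
#: the sign orientation
_SIGN_TOL = 1e-9
#: |lambda3 - lambda2| below this flags a (near-)degenerate Fiedler pair
_DEGENERACY_TOL = 1e-8

Edge = tuple[int, int]


def _normalize_edge(u: int, v: int) -> Edge:
    if u == v:
        raise SelfLoopError(f"self-loop at vertex {u}")
    return (u, v) if u < v else (v, u)


@dataclass(frozen=True)
class RAGTreeGraph:
    """A labeled unrooted tree describing an RNA's coarse topology.

    ``vertices`` holds the labels in ascending order; labels are 1-based
    and, for a graph built from a secondary structure, follow the 5'->3'
    order of the corresponding single-stranded elements.  Fragments
    produced by partitioning keep their parent's labels, so labels need
    not be contiguous.  A single, isolated vertex (n = 1, no edges) is a
    valid degenerate fragment; ``build_graph`` itself requires n >= 2.
    """

    vertices: tuple[int, ...]
    edges: frozenset[Edge]
    name: str | None = None

    def __post_init__(self) -> None:
        verts = tuple(sorted(self.vertices))
        object.__setattr__(self, "vertices", verts)
        if len(verts) == 0:
            raise GraphValidationError("graph needs at least one vertex")
        if len(set(verts)) != len(verts):
            raise GraphValidationError("duplicate vertex labels")
        if any(v < 1 for v in verts):
            raise LabelRangeError("vertex labels must be positive integers")
        vset = set(verts)
        for u, v in self.edges:
            if u == v:
                raise SelfLoopError(f"self-loop at vertex {u}")
            if u not in vset or v not in vset:
                raise LabelRangeError(f"edge ({u},{v}) references unknown vertex")
            if u > v:
                raise GraphValidationError("edges must be stored as (min, max)")
        n = len(verts)
        if len(self.edges) > n - 1:
            raise CycleError(f"{len(self.edges)} edges on {n} vertices: cycle present")
        if len(self.edges) < n - 1:
            raise DisconnectedError(
                f"{len(self.edges)} edges on {n} vertices: graph is disconnected"
            )
        if n > 1 and not self._connected():
            # |E| = n-1 but disconnected => some component has a cycle
            raise CycleError("graph has a cycle (and is disconnected)")

    def _connected(self) -> bool:
        adj = self.adjacency_lists()
        seen = {self.vertices[0]}
        stack = [self.vertices[0]]
        while stack:
            u = stack.pop()
            for w in adj[u]:
                if w not in seen:
                    seen.add(w)
                    stack.append(w)
        return len(seen) == self.n

    # -- basic accessors -------------------------------------------------

    @property
    def n(self) -> int:
        return len(self.vertices)

    def adjacency_lists(self) -> dict[int, list[int]]:
        adj: dict[int, list[int]] = {v: [] for v in self.vertices}
        for u, v in sorted(self.edges):
            adj[u].append(v)
            adj[v].append(u)
        return adj

    def degree(self, v: int) -> int:
        return sum(1 for e in self.edges if v in e)

    def degrees(self) -> dict[int, int]:
        deg = {v: 0 for v in self.vertices}
        for u, v in self.edges:
            deg[u] += 1
            deg[v] += 1
        return deg

    def index_of(self, label: int) -> int:
        """Position of ``label`` in the ascending vertex order."""
        i = int(np.searchsorted(self.vertices, label))
        if i >= self.n or self.vertices[i] != label:
            raise LabelRangeError(f"vertex {label} not in graph")
        return i

    def sorted_edges(self) -> list[Edge]:
        return sorted(self.edges)

    def relabeled(self, mapping: dict[int, int], name: str | None = None) -> "RAGTreeGraph":
        """Apply a vertex-label bijection; used by tests and the catalog."""
        edges = frozenset(_normalize_edge(mapping[u], mapping[v]) for u, v in self.edges)
        return RAGTreeGraph(tuple(mapping[v] for v in self.vertices), edges, name)

    def induced_subgraph(self, labels: Iterable[int], name: str | None = None) -> "RAGTreeGraph":
        lset = set(labels)
        edges = frozenset(e for e in self.edges if e[0] in lset and e[1] in lset)
        # the induced subgraph of a tree may be a forest; the caller is
        # responsible for splitting into components first when needed
        return RAGTreeGraph(tuple(sorted(lset)), edges, name)

    def components(self, labels: Iterable[int]) -> list["RAGTreeGraph"]:
        """Connected components of the induced subgraph on ``labels``."""
        lset = set(labels)
        adj: dict[int, list[int]] = {v: [] for v in lset}
        for u, v in self.edges:
            if u in lset and v in lset:
                adj[u].append(v)
                adj[v].append(u)
        comps: list[RAGTreeGraph] = []
        unseen = set(lset)
        while unseen:
            start = min(unseen)
            comp = {start}
            stack = [start]
            while stack:
                x = stack.pop()
                for w in adj[x]:
                    if w not in comp:
                        comp.add(w)
                        stack.append(w)
            unseen -= comp
            comps.append(self.induced_subgraph(comp))
        comps.sort(key=lambda g: g.vertices[0])
        return comps

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        tag = f" {self.name!r}" if self.name else ""
        return f"<RAGTreeGraph{tag} n={self.n} edges={self.sorted_edges()}>"


def build_graph(
    edge_pairs: Iterable[tuple[int, int]], n: int, name: str | None = None
) -> RAGTreeGraph:
    """Validate an edge list into a tree graph on vertices 1..n.

    Raises a distinct :class:`GraphValidationError` subclass for each
    failure mode: self-loop, duplicate edge, out-of-range label, cycle,
    or disconnection.
    """
    if n < 2:
        raise GraphValidationError(f"n must be >= 2, got {n}")
    seen: set[Edge] = set()
    for u, v in edge_pairs:
        if not (1 <= u <= n and 1 <= v <= n):
            raise LabelRangeError(f"edge ({u},{v}) outside 1..{n}")
        e = _normalize_edge(u, v)
        if e in seen:
            raise DuplicateEdgeError(f"duplicate edge {e}")
        seen.add(e)
    return RAGTreeGraph(tuple(range(1, n + 1)), frozenset(seen), name)


def laplacian(g: RAGTreeGraph) -> np.ndarray:
    """Graph Laplacian L = D - A as an integer matrix.

    Rows/columns follow the ascending vertex-label order of ``g``.
    Diagonal entries are vertex degrees; entry (i, j) is -1 iff vertices
    i and j are adjacent.  Every row sums to zero.
    """
    n = g.n
    L = np.zeros((n, n), dtype=np.int64)
    for u, v in g.edges:
        i, j = g.index_of(u), g.index_of(v)
        L[i, i] += 1
        L[j, j] += 1
        L[i, j] -= 1
        L[j, i] -= 1
    return L


def orient_sign(vec: np.ndarray, tol: float = _SIGN_TOL) -> np.ndarray:
    """Fix the +/- ambiguity: first component of magnitude > tol is positive."""
    for x in vec:
        if abs(x) > tol:
            return -vec if x < 0 else vec.copy()
    return vec.copy()


@dataclass(frozen=True)
class LaplacianSpectrum:
    """Full eigendecomposition of a tree Laplacian with the Fiedler pair.

    ``eigenvalues`` ascend; ``eigenvectors[:, k]`` is the unit eigenvector
    for ``eigenvalues[k]``.  ``mu2`` is sign-oriented so that its first
    nonzero component is positive.  ``multiplicity_flag`` is raised when
    lambda2 is (near-)degenerate — the Fiedler vector is then not unique
    and downstream cuts carry a reproducibility warning.
    """

    matrix: np.ndarray
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    lambda2: float
    mu2: np.ndarray
    multiplicity_flag: bool
    graph: RAGTreeGraph = field(repr=False)

    def component(self, label: int) -> float:
        """Fiedler-vector component for the vertex with this label."""
        return float(self.mu2[self.graph.index_of(label)])


def spectrum(g: RAGTreeGraph, degeneracy_tol: float = _DEGENERACY_TOL) -> LaplacianSpectrum:
    """Dense symmetric eigendecomposition of the Laplacian of ``g``.

    Requires n >= 2 (lambda2 is undefined for a single vertex).
    """
    if g.n < 2:
        raise GraphValidationError("spectrum requires at least 2 vertices")
    L = laplacian(g)
    evals, evecs = np.linalg.eigh(L.astype(float))
    mu2 = orient_sign(evecs[:, 1])
    flag = bool(g.n > 2 and abs(evals[2] - evals[1]) < degeneracy_tol)
    return LaplacianSpectrum(
        matrix=L,
        eigenvalues=evals,
        eigenvectors=evecs,
        lambda2=float(evals[1]),
        mu2=mu2,
        multiplicity_flag=flag,
        graph=g,
    )


def fiedler(g: RAGTreeGraph) -> tuple[float, np.ndarray]:
    """Convenience accessor: (lambda2, mu2) of ``g``, mu2 sign-oriented."""
    s = spectrum(g)
    return s.lambda2, s.mu2


# -- edge-list files -----------------------------------------------------
#
# Format: one edge per line, two whitespace-separated 1-based integers;
# '#' starts a comment; an optional header line "n=<int>" fixes the vertex
# count (otherwise the maximum label is used).


def read_edge_list(source: str | Path, name: str | None = None) -> RAGTreeGraph:
    """Read a tree graph from an edge-list file or a literal text block."""
    path = Path(source)
    try:
        is_file = path.is_file()
    except OSError:  # e.g. embedded newlines in a literal
        is_file = False
    text = path.read_text() if is_file else str(source)
    if name is None and is_file:
        name = path.stem
    n_decl: int | None = None
    pairs: list[tuple[int, int]] = []
    for lineno, raw in enumerate(text.splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.lower().startswith("n="):
            n_decl = int(line[2:].strip())
            continue
        fields = line.split()
        if len(fields) != 2:
            raise GraphValidationError(f"line {lineno}: expected two labels, got {raw!r}")
        try:
            u, v = int(fields[0]), int(fields[1])
        except ValueError as exc:
            raise GraphValidationError(f"line {lineno}: non-integer label in {raw!r}") from exc
        pairs.append((u, v))
    if not pairs:
        raise GraphValidationError("edge list is empty")
    n = n_decl if n_decl is not None else max(max(u, v) for u, v in pairs)
    return build_graph(pairs, n, name)


def write_edge_list(g: RAGTreeGraph, path: str | Path) -> None:
    lines = [f"# {g.name}" if g.name else "# ragcut edge list"]
    lines.append(f"n={g.n}")
    lines += [f"{u} {v}" for u, v in g.sorted_edges()]
    Path(path).write_text("\n".join(lines) + "\n")


def to_networkx(g: RAGTreeGraph):  # pragma: no cover - thin optional bridge
    """Export to a networkx.Graph (networkx is not a runtime dependency)."""
    import networkx as nx

    G = nx.Graph(name=g.name or "")
    G.add_nodes_from(g.vertices)
    G.add_edges_from(g.edges)
    return G
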