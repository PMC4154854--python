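"""Recursive gap-cut decomposition and inverse assembly planning.

Applying the gap cut iteratively — recomputing the Fiedler vector of
each fragment — decomposes a large RNA tree graph into *minimal
modules*: star-shaped fragments, i.e. single edges (a hairpin stem with
its loop and dangling end) or k-leaf stars (k-way junctions).  The
binary record of the decomposition, read bottom-up, is a hierarchical
assembly plan: each internal node names the single-stranded vertex
shared by its two overlap-mode fragments, and merging fragments through
their shared vertices, deepest cuts first, rebuilds the original graph
exactly.
"""

from __future__ import annotations

from collections.abc import Callable, Iterable, Sequence
from dataclasses import dataclass

from .errors import AssemblyError, PartitionError, ReplayError
from .graph import RAGTreeGraph
from .partition import CutResult, extract_fragments, gap_cut, shared_vertex

__all__ = [
    "PartitionNode",
    "PartitionTree",
    "AssemblyStep",
    "is_minimal_module",
    "decompose",
    "replay_splits",
    "assembly_plan",
    "merge_on_shared_vertex",
    "to_dot",
]

StopPredicate = Callable[[RAGTreeGraph], bool]


def is_minimal_module(g: RAGTreeGraph) -> bool:
    """True iff ``g`` is a star: at most one vertex of degree >= 2.

    Covers the two terminal module shapes of the decomposition: the
    single edge (hairpin, graph 2_1) and the k-leaf star (k-way
    junction, e.g. the three-way junction 4_2).  A lone vertex is
    trivially minimal.
    """
    return sum(1 for d in g.degrees().values() if d >= 2) <= 1


@dataclass
class PartitionNode:
    """One node of the binary decomposition record."""

    graph: RAGTreeGraph
    cut: CutResult | None = None
    children: tuple["PartitionNode", "PartitionNode"] | None = None

    @property
    def is_leaf(self) -> bool:
        return self.children is None


@dataclass
class PartitionTree:
    """Binary record of an iterative decomposition.

    ``leaves`` are the terminal fragments in breadth-first, 5'->3'
    (smallest-contained-label) order; every leaf satisfies the stop
    predicate the tree was built with.  Fragments keep the vertex labels
    of the root graph throughout.
    """

    root: PartitionNode
    mode: str

    def _levels(self) -> list[list[PartitionNode]]:
        levels, frontier = [], [self.root]
        while frontier:
            levels.append(frontier)
            nxt: list[PartitionNode] = []
            for node in frontier:
                if node.children is not None:
                    nxt.extend(node.children)
            frontier = nxt
        return levels

    def bfs_nodes(self) -> list[PartitionNode]:
        return [n for level in self._levels() for n in level]

    @property
    def leaves(self) -> list[RAGTreeGraph]:
        out: list[RAGTreeGraph] = []

        def walk(node: PartitionNode) -> None:
            if node.is_leaf:
                out.append(node.graph)
            else:
                for child in node.children:
                    walk(child)

        walk(self.root)
        return out

    @property
    def depth(self) -> int:
        return len(self._levels()) - 1

    @property
    def cuts(self) -> list[CutResult]:
        return [n.cut for n in self.bfs_nodes() if n.cut is not None]


def _single_fragments(cut: CutResult) -> tuple[RAGTreeGraph, RAGTreeGraph]:
    fa, fb = cut.fragments
    if isinstance(fa, tuple) or isinstance(fb, tuple):
        raise PartitionError(
            "multi-edge cut produced disconnected sides; cannot recurse"
        )
    return fa, fb


def _ordered_children(
    a: RAGTreeGraph, b: RAGTreeGraph
) -> tuple[RAGTreeGraph, RAGTreeGraph]:
    # deterministic 5'->3' ordering: fragment holding the smaller label first;
    # overlap fragments share one vertex, so break ties on the second label
    return (a, b) if (a.vertices < b.vertices) else (b, a)


def decompose(
    g: RAGTreeGraph,
    stop: StopPredicate = is_minimal_module,
    mode: str = "overlap",
    cut_fn: Callable[[RAGTreeGraph], CutResult] = gap_cut,
) -> PartitionTree:
    """Recursively bisect ``g`` until every fragment satisfies ``stop``.

    The Fiedler vector is recomputed on every fragment.  Traversal is
    breadth-first with children ordered 5'->3'; the result is
    reproducible byte-for-byte.  Recursion is bounded by n - 1 cuts
    (every fragment has strictly fewer edges than its parent).
    """
    root = PartitionNode(g)
    frontier = [root]
    cuts_done, max_cuts = 0, max(g.n - 1, 1)
    while frontier:
        nxt: list[PartitionNode] = []
        for node in frontier:
            if stop(node.graph):
                continue
            if cuts_done >= max_cuts:  # pragma: no cover - safety net
                raise PartitionError("decomposition exceeded its recursion bound")
            cut = extract_fragments(node.graph, cut_fn(node.graph), mode)
            fa, fb = _single_fragments(cut)
            fa, fb = _ordered_children(fa, fb)
            node.cut = cut
            node.children = (PartitionNode(fa), PartitionNode(fb))
            nxt.extend(node.children)
            cuts_done += 1
        frontier = nxt
    return PartitionTree(root, mode)


def replay_splits(
    g: RAGTreeGraph,
    recorded: Iterable[tuple[Iterable[int], Iterable[int]]],
    mode: str = "overlap",
) -> PartitionTree:
    """Build a partition tree from recorded bipartitions, bypassing spectra.

    Each recorded pair must bipartition the vertex set of some current
    leaf fragment; overlap extraction (the default) then applies the
    shared-vertex augmentation exactly as in a spectral decomposition.
    Used to regression-test bookkeeping against published decompositions.
    """
    root = PartitionNode(g)
    open_leaves = [root]
    for pair in recorded:
        set_a, set_b = frozenset(pair[0]), frozenset(pair[1])
        if set_a & set_b or not set_a or not set_b:
            raise ReplayError(f"recorded pair {sorted(set_a)}/{sorted(set_b)} "
                              "is not a bipartition")
        union = set_a | set_b
        target = next(
            (n for n in open_leaves if set(n.graph.vertices) == union), None
        )
        if target is None:
            raise ReplayError(
                f"no open fragment has vertex set {sorted(union)}"
            )
        cut_edges = tuple(
            e for e in target.graph.sorted_edges()
            if (e[0] in set_a) != (e[1] in set_a)
        )
        cut = CutResult(
            method="replay",
            s=float("nan"),
            part_a=set_a,
            part_b=set_b,
            cut_edges=cut_edges,
        )
        cut = extract_fragments(target.graph, cut, mode)
        fa, fb = _single_fragments(cut)
        fa, fb = _ordered_children(fa, fb)
        target.cut = cut
        target.children = (PartitionNode(fa), PartitionNode(fb))
        open_leaves.remove(target)
        open_leaves.extend(target.children)
    return PartitionTree(root, mode)


# -- assembly ------------------------------------------------------------


@dataclass(frozen=True)
class AssemblyStep:
    """One merge of the inverse (bottom-up) cutting procedure."""

    left_id: str
    right_id: str
    shared_vertex: int
    product_id: str
    left_vertices: tuple[int, ...]
    right_vertices: tuple[int, ...]
    product_vertices: tuple[int, ...]


def merge_on_shared_vertex(a: RAGTreeGraph, b: RAGTreeGraph) -> RAGTreeGraph:
    """Union two fragments that share exactly one vertex."""
    common = set(a.vertices) & set(b.vertices)
    if len(common) != 1:
        raise AssemblyError(
            f"fragments share {len(common)} vertices; expected exactly 1"
        )
    edges = set(a.edges) | set(b.edges)
    if len(edges) != len(a.edges) + len(b.edges):
        raise AssemblyError("fragment edge sets are not disjoint")
    return RAGTreeGraph(
        tuple(sorted(set(a.vertices) | set(b.vertices))), frozenset(edges)
    )


def _fragment_id(g: RAGTreeGraph, namer: Callable[[RAGTreeGraph], str | None]) -> str:
    rag_id = namer(g)
    labels = ",".join(map(str, g.vertices))
    return f"{rag_id or f'{g.n}_?'}{{{labels}}}"


def assembly_plan(
    tree: PartitionTree,
    namer: Callable[[RAGTreeGraph], str | None] | None = None,
) -> list[AssemblyStep]:
    """Internal nodes of an overlap-mode tree, deepest first, as merges.

    Executing the steps in order — each merging two fragments through
    their shared vertex — reproduces the root graph exactly.  ``namer``
    maps a fragment to a topology identifier (e.g. catalog lookup); by
    default fragments are named by vertex count and label set.
    """
    if tree.mode != "overlap":
        raise AssemblyError(
            "assembly requires an overlap-mode tree (strict fragments share "
            "no vertices)"
        )
    if namer is None:
        namer = lambda g: None  # noqa: E731
    steps: list[AssemblyStep] = []
    for node in reversed(tree.bfs_nodes()):
        if node.is_leaf:
            continue
        left, right = (c.graph for c in node.children)
        steps.append(
            AssemblyStep(
                left_id=_fragment_id(left, namer),
                right_id=_fragment_id(right, namer),
                shared_vertex=shared_vertex(node.cut),
                product_id=_fragment_id(node.graph, namer),
                left_vertices=left.vertices,
                right_vertices=right.vertices,
                product_vertices=node.graph.vertices,
            )
        )
    return steps


def execute_plan(
    leaves: Sequence[RAGTreeGraph], steps: Sequence[AssemblyStep]
) -> RAGTreeGraph:
    """Run an assembly plan on terminal fragments; returns the root graph."""
    pool = {g.vertices: g for g in leaves}
    for step in steps:
        a = pool.pop(step.left_vertices)
        b = pool.pop(step.right_vertices)
        merged = merge_on_shared_vertex(a, b)
        if step.shared_vertex not in set(a.vertices) & set(b.vertices):
            raise AssemblyError("plan names a vertex the fragments do not share")
        pool[merged.vertices] = merged
    if len(pool) != 1:
        raise AssemblyError(f"{len(pool)} fragments remain after the plan")
    return next(iter(pool.values()))


def to_dot(tree: PartitionTree, namer=None) -> str:
    """Graphviz DOT rendering of a partition tree (for documentation)."""
    if namer is None:
        namer = lambda g: None  # noqa: E731
    lines = ["digraph partition_tree {", '  node [shape=box, fontname="monospace"];']
    ids: dict[int, str] = {}
    for i, node in enumerate(tree.bfs_nodes()):
        ids[id(node)] = f"n{i}"
        label = _fragment_id(node.graph, namer)
        if node.cut is not None and node.cut.method != "replay":
            label += f"\\n{node.cut.method} s={node.cut.s:.3f}"
        lines.append(f'  n{i} [label="{label}"];')
    for node in tree.bfs_nodes():
        if node.children is not None:
            for child in node.children:
                lines.append(f"  {ids[id(node)]} -> {ids[id(child)]};")
    lines.append("}")
    return "\n".join(lines)
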