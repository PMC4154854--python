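"""Spectral bisection of RNA tree graphs: median, sign, and gap cuts.

All three rules threshold the Fiedler vector mu2 at a splitting value s
and put every vertex i with component nu_i <= s into part A, the rest
into the complement.  The rules differ only in how s is chosen:

* median cut  — s is the median of the components (for even n the mean of
  the two central sorted values, so s never coincides with a component;
  for odd n the central component itself, which then falls in part A);
* sign cut    — s = 0, separating negative from positive components
  (components exactly zero join the <= 0 side);
* gap cut     — s is the midpoint of the largest gap between consecutive
  sorted components; ties on the gap width (within 1e-9) are broken
  toward the gap at smaller component values.

Because an eigenvector is only defined up to sign, the named cuts first
fix the orientation of mu2 (first nonzero component positive), and every
partition is reported as an unordered pair, so results are invariant
under sign flips of the input vector.

Fragment extraction supports two conventions.  *Strict* extraction drops
the cut edges and returns the induced subgraph of each part.  *Overlap*
extraction keeps the single cut edge in exactly one fragment together
with a duplicate of its far endpoint, so the two fragments are both
valid RNA-module graphs sharing exactly one vertex — the convention
needed for hierarchical reassembly, where the shared vertex is the
single strand joining the two modules.
"""

from __future__ import annotations

from collections.abc import Sequence
from dataclasses import dataclass, replace

import numpy as np

from .errors import EmptyPartError, MultiCutError, PartitionError
from .graph import Edge, RAGTreeGraph, orient_sign, spectrum

__all__ = [
    "CutResult",
    "threshold_split",
    "median_cut",
    "sign_cut",
    "gap_cut",
    "cut",
    "extract_fragments",
]

_GAP_TIE_TOL = 1e-9

Fragment = RAGTreeGraph | tuple[RAGTreeGraph, ...]


@dataclass(frozen=True)
class CutResult:
    """One spectral bisection of a tree graph.

    ``part_a`` is exactly ``{i : nu_i <= s}`` for spectral cuts (for
    replayed cuts ``s`` is NaN).  ``fragments`` is filled by
    :func:`extract_fragments`; each element is a single graph, or a tuple
    of connected components when a strict multi-edge cut disconnects a
    side.
    """

    method: str
    s: float
    part_a: frozenset[int]
    part_b: frozenset[int]
    cut_edges: tuple[Edge, ...]
    gap_width: float | None = None
    degenerate_warning: bool = False
    warnings: tuple[str, ...] = ()
    fragments: tuple[Fragment, Fragment] | None = None

    @property
    def parts(self) -> tuple[frozenset[int], frozenset[int]]:
        return (self.part_a, self.part_b)

    def unordered_parts(self) -> frozenset[frozenset[int]]:
        """The partition as an unordered pair (orientation-invariant view)."""
        return frozenset((self.part_a, self.part_b))


def threshold_split(
    g: RAGTreeGraph,
    mu2: Sequence[float],
    s: float,
    method_tag: str = "threshold",
    *,
    gap_width: float | None = None,
    degenerate_warning: bool = False,
) -> CutResult:
    """Split ``g`` at splitting value ``s`` on the given Fiedler vector.

    ``mu2`` is taken in the caller's orientation and must be aligned with
    the ascending vertex order of ``g``.  Raises :class:`EmptyPartError`
    when the threshold leaves either side empty.
    """
    vec = np.asarray(mu2, dtype=float)
    if vec.shape != (g.n,):
        raise PartitionError(f"mu2 has length {vec.size}, graph has {g.n} vertices")
    part_a = frozenset(v for v, x in zip(g.vertices, vec) if x <= s)
    part_b = frozenset(g.vertices) - part_a
    if not part_a or not part_b:
        raise EmptyPartError(f"splitting value s={s} leaves one part empty")
    cut_edges = tuple(
        e for e in g.sorted_edges() if (e[0] in part_a) != (e[1] in part_a)
    )
    warnings: tuple[str, ...] = ()
    if degenerate_warning:
        warnings = ("lambda2 is (near-)degenerate: the Fiedler vector, and hence "
                    "this partition, is not unique",)
    return CutResult(
        method=method_tag,
        s=float(s),
        part_a=part_a,
        part_b=part_b,
        cut_edges=cut_edges,
        gap_width=gap_width,
        degenerate_warning=degenerate_warning,
        warnings=warnings,
    )


def _oriented_mu2(g: RAGTreeGraph, mu2: Sequence[float] | None) -> tuple[np.ndarray, bool]:
    if mu2 is None:
        sp = spectrum(g)
        return sp.mu2, sp.multiplicity_flag
    vec = orient_sign(np.asarray(mu2, dtype=float))
    return vec, False


def median_cut(g: RAGTreeGraph, mu2: Sequence[float] | None = None) -> CutResult:
    """Bisection at the median of the Fiedler-vector components."""
    vec, flag = _oriented_mu2(g, mu2)
    if float(np.ptp(vec)) <= _GAP_TIE_TOL:
        raise PartitionError("all Fiedler components equal; median cut undefined")
    s = float(np.median(vec))
    return threshold_split(g, vec, s, "median", degenerate_warning=flag)


def sign_cut(g: RAGTreeGraph, mu2: Sequence[float] | None = None) -> CutResult:
    """Bisection at s = 0: negative (and zero) components vs positive."""
    vec, flag = _oriented_mu2(g, mu2)
    return threshold_split(g, vec, 0.0, "sign", degenerate_warning=flag)


def gap_cut(g: RAGTreeGraph, mu2: Sequence[float] | None = None) -> CutResult:
    """Bisection at the midpoint of the largest gap in the sorted components."""
    vec, flag = _oriented_mu2(g, mu2)
    order = np.sort(vec)
    gaps = np.diff(order)
    if gaps.size == 0 or float(gaps.max()) <= 0.0:
        raise PartitionError("no gap between Fiedler components; gap cut undefined")
    widest = float(gaps.max())
    # first maximal gap within tolerance = the one at smaller values
    k = int(np.flatnonzero(gaps >= widest - _GAP_TIE_TOL)[0])
    s = float((order[k] + order[k + 1]) / 2.0)
    return threshold_split(g, vec, s, "gap", gap_width=float(gaps[k]),
                           degenerate_warning=flag)


_METHODS = {"median": median_cut, "sign": sign_cut, "gap": gap_cut}


def cut(g: RAGTreeGraph, method: str, mu2: Sequence[float] | None = None) -> CutResult:
    """Dispatch on the method name ('median', 'sign', or 'gap')."""
    try:
        fn = _METHODS[method]
    except KeyError:
        raise PartitionError(f"unknown cut method {method!r}") from None
    return fn(g, mu2)


# -- fragment extraction -------------------------------------------------


def _augmented_side(g: RAGTreeGraph, cut_result: CutResult) -> frozenset[int]:
    """Which part receives the cut edge (plus the far endpoint) in overlap mode.

    Rules, in order: (i) a side whose induced subgraph has no edge (a lone
    vertex) is augmented, so it becomes a valid single-edge module;
    (ii) otherwise the side whose cut endpoint has the higher degree in
    the parent graph — the cut helix stays attached to the junction;
    (iii) on a tie, the side containing the parent's maximum-degree
    vertex; (iv) on a further tie, the side containing the smaller label.
    """
    (u, v) = cut_result.cut_edges[0]
    part_u = cut_result.part_a if u in cut_result.part_a else cut_result.part_b
    part_v = cut_result.part_b if part_u is cut_result.part_a else cut_result.part_a
    deg = g.degrees()

    def side_has_edge(part: frozenset[int]) -> bool:
        return any(e[0] in part and e[1] in part for e in g.edges)

    u_has, v_has = side_has_edge(part_u), side_has_edge(part_v)
    if u_has != v_has:
        return part_v if u_has else part_u
    if not u_has and not v_has:
        raise PartitionError(
            "overlap extraction of a single-edge graph is undefined "
            "(both sides are lone vertices)"
        )
    if deg[u] != deg[v]:
        return part_u if deg[u] > deg[v] else part_v
    max_deg = max(deg.values())
    u_max = any(deg[x] == max_deg for x in part_u)
    v_max = any(deg[x] == max_deg for x in part_v)
    if u_max != v_max:
        return part_u if u_max else part_v
    return part_u if min(part_u) < min(part_v) else part_v


def extract_fragments(
    g: RAGTreeGraph, cut_result: CutResult, mode: str = "strict"
) -> CutResult:
    """Materialize the two fragments of a cut; returns an updated CutResult.

    strict:  each fragment is the induced subgraph on its part; cut edges
             are dropped.  If a multi-edge cut disconnects a side, that
             side is returned as a tuple of connected components and a
             warning is recorded.
    overlap: requires exactly one cut edge; the edge is kept in one
             fragment together with a duplicate of its far endpoint, so
             fragment edge sets partition the parent's edge set exactly
             and the fragments share exactly one vertex.
    """
    if mode not in ("strict", "overlap"):
        raise PartitionError(f"unknown extraction mode {mode!r}")
    warnings = cut_result.warnings
    if mode == "strict":
        frags: list[Fragment] = []
        multi = False
        for part in cut_result.parts:
            comps = g.components(part)
            if len(comps) == 1:
                frags.append(comps[0])
            else:
                multi = True
                frags.append(tuple(comps))
        if multi:
            warnings = warnings + (
                f"{len(cut_result.cut_edges)}-edge cut disconnects a side; "
                "fragments returned as connected components",
            )
        return replace(cut_result, fragments=(frags[0], frags[1]), warnings=warnings)

    if len(cut_result.cut_edges) != 1:
        raise MultiCutError(
            f"overlap extraction needs a single cut edge, got "
            f"{len(cut_result.cut_edges)}: shared-vertex semantics undefined"
        )
    (u, v) = cut_result.cut_edges[0]
    aug = _augmented_side(g, cut_result)
    other = cut_result.part_b if aug is cut_result.part_a else cut_result.part_a
    far = u if u in other else v
    frag_aug = g.induced_subgraph(set(aug) | {far})
    frag_other = g.induced_subgraph(other)
    pair = (
        (frag_aug, frag_other)
        if aug is cut_result.part_a
        else (frag_other, frag_aug)
    )
    return replace(cut_result, fragments=pair, warnings=warnings)


def shared_vertex(cut_result: CutResult) -> int:
    """The vertex common to both overlap-mode fragments of a cut."""
    if cut_result.fragments is None:
        raise PartitionError("fragments not extracted")
    fa, fb = cut_result.fragments
    if isinstance(fa, tuple) or isinstance(fb, tuple):
        raise PartitionError("multi-component fragments have no shared vertex")
    common = set(fa.vertices) & set(fb.vertices)
    if len(common) != 1:
        raise PartitionError(
            f"expected exactly one shared vertex, found {sorted(common)}"
        )
    return common.pop()
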