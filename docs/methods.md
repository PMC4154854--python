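# Methods

## Graph model

An RNA secondary structure is coarse-grained as an unrooted labeled
tree: every helical stem with more than one base pair is an edge; every
single-stranded element (hairpin loop, internal loop or bulge with more
than one unmatched nucleotide or an unstable pair, junction, exterior
strand) is a vertex. Vertices are labeled 1…n in 5′→3′ order of each
element's first residue. Nested (pseudoknot-free) base pairing
guarantees the element graph is a tree, which the conversion asserts:
vertices = helices + 1 always holds.

The Laplacian is L = D − A with integer entries; the sign convention is
fixed by positive semidefiniteness (all printed second eigenvalues are
positive, and λ₁ = 0 for the constant vector). Eigenpairs come from a
dense symmetric solver (`numpy.linalg.eigh`); graphs in this domain
have at most a few dozen vertices, so sparse or iterative methods would
buy nothing.

### Numerical conventions

* **Zero tests** use 1e−9 (zero-sum of µ₂, λ₁ = 0, gap ties);
  **residual tests** use 1e−8 (‖L·µ₂ − λ₂·µ₂‖).
* **Eigenvector sign.** µ₂ is only defined up to ±1. We orient it so
  that its first component of magnitude > 1e−9 is positive, and we
  report every partition as an unordered pair, so all cut results are
  invariant under sign flips of the input vector. One visible
  consequence: for the 3-vertex path the center component is exactly 0
  and the ν ≤ 0 membership rule places it with the negative side *of
  the oriented vector*, giving the pair {1}/{2,3}.
* **Degenerate λ₂.** Stars and other symmetric trees have λ₂ with
  multiplicity > 1; the Fiedler vector is then a basis choice, not a
  property of the graph. The spectrum flags |λ₃ − λ₂| < 1e−8 and every
  cut derived from a flagged spectrum carries a reproducibility
  warning. The partition itself is still computed from the solver's
  (deterministic) vector.
* **Printed-value comparisons** round to two decimals with a ±0.01
  tolerance, because exact components can sit on a rounding boundary
  (the 6_5 branch leaves are 0.31504… → printed 0.32).

## Cuts

All three rules share the membership convention part A = {i : νᵢ ≤ s}:

* **median** — s = median of the components; for even n the mean of
  the two central sorted values (so s never coincides with a
  component), for odd n the central component itself, which then falls
  in part A;
* **sign** — s = 0; zero components join part A;
* **gap** — sort the components, take the midpoint of the widest
  consecutive gap; ties within 1e−9 break toward the gap at smaller
  values (the convention had to be fixed somewhere; smaller values keep
  the rule stable under the orientation above).

**Known discrepancy.** For graph 6_2 the two largest gaps are 0.3644
(splitting {1,2,3}/{4,5,6}) and 0.3380 (splitting {1,2,3,4}/{5,6}).
The published partition for the gap cut of 6_2 is the *second* of
these; the strict largest-gap rule implemented here selects the first.
No criterion for preferring the narrower gap is stated anywhere, so the
implementation follows the strict rule and documents the difference
rather than special-casing one graph. All other published single cuts
(6_1, 6_5, and the first cut of 10_19) are reproduced exactly. The
discrepancy propagates to the live iterative decomposition of 10_19:
its 6_2-shaped fragment {1,6,7,8,9,10} splits down the middle into
4_2 + 3_1 (both already minimal), so `decompose` terminates with four
modules where the published decomposition, reproducible via
`replay_splits`, records five.

## Fragment extraction

*Strict* mode drops the cut edges and returns induced subgraphs — the
right view for reporting a bisection. A median cut of a branched tree
can sever several edges; strict mode then returns each side's connected
components with a warning, while overlap mode refuses (shared-vertex
semantics is undefined for multi-edge cuts).

*Overlap* mode models how RNA modules physically share the connecting
single strand: the single cut edge is kept in exactly one fragment
together with a duplicate of its far endpoint, so fragment edge sets
partition the parent's edges and the fragments share exactly one
vertex. Which side keeps the cut edge is decided by, in order:
(i) a lone-vertex side is augmented (it must become a single-edge
module); (ii) otherwise the side whose cut endpoint has the higher
parent degree — the severed helix stays attached to the junction it
emanates from; (iii) the side containing the parent's maximum-degree
vertex; (iv) the side with the smaller label. Rules (ii)–(iv) were
chosen as the simplest deterministic policy that reproduces all four
recorded module extractions of the 10_19 decomposition; nothing in the
method's published description fixes them, and alternative tie-breaks
would change only which of two topologically equivalent overlap
fragments carries the shared helix.

## Iterative decomposition and assembly

`decompose` applies gap cut + overlap extraction breadth-first,
re-solving the eigenproblem on every fragment (the only reading
consistent with applying *the algorithm* iteratively), until every
fragment passes the stop predicate. The default stop is the **star
test** — at most one vertex of degree ≥ 2 — which accepts exactly the
terminal modules observed in practice (single edges and k-way
junctions) without needing a database; a catalog-membership predicate
is available where "stop at any known topology" is wanted. Children are
ordered by smallest contained label, so trees are reproducible
byte-for-byte. Every fragment has strictly fewer edges than its parent,
bounding the recursion by n − 1 cuts.

`replay_splits` rebuilds a partition tree from recorded bipartitions
instead of spectra; it exists so that a published decomposition can be
regression-tested purely as bookkeeping (matching fragments by vertex
set, applying the same overlap augmentation).

`assembly_plan` emits the internal nodes deepest-first (reverse
breadth-first). Each step merges two fragments through their shared
vertex — vertex sets unite, edge sets concatenate disjointly — and
executing the whole plan reproduces the root graph exactly, which is
property-tested on random trees.

## Catalog

Canonical forms are AHU encodings rooted at the tree centroid (for
bicentroidal trees the lexicographically smaller of the two rooted
strings), so string equality is isomorphism. Enumeration proceeds by
leaf extension: every n-vertex class arises from deleting a leaf of
some (n+1)-vertex tree, so extending each (n−1)-class at every vertex
and deduplicating by canonical form is exhaustive, and costs only
(classes × n) canonicalizations per level — enumerating all 235
11-vertex classes takes well under a second, where generating all
11⁹ ≈ 2.4·10⁹ labeled trees from Prüfer sequences would not finish.
(Exhaustive Prüfer generation *is* used, at n ≤ 7, as the independent
oracle in the tests.) IDs `n_k` rank same-order classes by ascending
λ₂; exact λ₂ ties between non-isomorphic trees occur (e.g. several
7–11-vertex pairs tie at 2 − 2cos(π/5) and relatives), and are broken
by canonical string so the numbering is deterministic. The derived
ranks reproduce every ID used by the reference set, including `10_19`.

## Secondary-structure conversion

Decisions where the coarse-graining rules leave latitude:

* **Helix rule**: a stem needs more than one base pair. Maximal stacked
  runs separated by a single unmatched nucleotide on one strand (1×0
  bulge) merge into one stem; after merging, single-pair stems are
  discarded and their residues treated as unpaired.
* **Unstable pairs**: when a sequence is provided, an annotated pair
  outside {AU, GC, GU} is treated as unpaired (the input carries no
  thermodynamics, so non-canonical pairing is the operational proxy for
  "unstable"); without a sequence, all annotated pairs count.
* **Vertex rule**: any loop region between stems with ≥ 2 unmatched
  nucleotides total (1×1, 0×2, larger) is a vertex; junctions and
  hairpin loops are vertices regardless of their unpaired count.
* **Exterior strand**: always exactly one vertex, even with no unpaired
  exterior residues — required for a lone hairpin to map to the
  single-edge graph (stem edge joining hairpin loop and dangling end),
  and it is the element that connects multiple top-level stems.
* **Pseudoknots** raise an error naming the crossing pairs; dot-bracket
  input accepts `()` only (higher bracket orders exist to encode
  crossings, which trees cannot represent).

## Synthetic data

Property tests draw uniform labeled trees from seeded Prüfer sequences
(n = 4…16 for spectral invariants, 5…14 for decomposition round trips,
200 and 100 draws respectively — sizes chosen to bracket the 4–11
vertex range of solved RNA tree topologies with headroom). Random
nested dot-bracket strings exercise hairpins, internal loops,
junctions, 1-nt bulges, and isolated pairs. What these do **not**
emulate: real RNAs occupy a biased, sparse subset of tree space
(45 solved topologies across 4–11 vertices), their stems have
sequence-dependent stability, and bulge/loop classification on real
annotations depends on the annotation tool's conventions. Passing
property tests therefore certifies the graph-theoretic machinery —
spectra, cuts, conservation laws, reassembly — not biological
relevance of any particular partition.

## Known limitations

* Pseudoknots and dual graphs are out of scope; so is deciding which
  catalog topologies correspond to solved structures.
* For degenerate λ₂ the reported cut depends on the eigensolver's basis
  choice; it is flagged, not resolved.
* The 6_2 gap-cut discrepancy above is inherent to the strict
  largest-gap rule.
* Catalog enumeration is capped at 12 vertices; beyond that fragment
  naming falls back to vertex counts.
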