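"""RNA secondary structures and their conversion to RAG tree graphs.

Conversion rules (coarse-grained tree representation):

* an **edge** is a double-stranded helical stem with more than one base
  pair.  Maximal stacks separated only by a single unmatched nucleotide
  on one strand (a 1x0 bulge) count as one stem; isolated pairs (stacks
  of length 1 after merging) are discarded and their residues treated as
  unpaired;
* a **vertex** is a single-stranded element: hairpin loop, internal loop
  or bulge with more than one unmatched nucleotide (or an unstable,
  i.e. non-canonical, annotated pair), junction, or the 5'/3' exterior
  strand.  The exterior always contributes exactly one vertex, so a lone
  hairpin maps to the single-edge graph 2_1 (hairpin loop + dangling
  end).

Vertices are numbered 5'->3' by each element's first residue.  Only
pseudoknot-free (fully nested) structures are representable as trees;
crossing pairs raise :class:`~ragcut.errors.PseudoknotError`.

Supported input formats: dot-bracket (``()`` brackets only, optional
sequence line), CT, and BPSEQ (standard 1-based column layouts).
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import NoHelixError, PseudoknotError, StructureFormatError
from .graph import RAGTreeGraph

__all__ = [
    "SecondaryStructure",
    "Helix",
    "StructuralElement",
    "parse_structure",
    "find_helices",
    "classify_elements",
    "to_rag_tree",
]

#: Watson-Crick and wobble pairs; anything else annotated in the input is
#: treated as an unstable pair, i.e. as unpaired, when sequence is known
CANONICAL_PAIRS = {"AU", "UA", "GC", "CG", "GU", "UG"}

Pair = tuple[int, int]


@dataclass(frozen=True)
class SecondaryStructure:
    """A base-pairing annotation: 1-based, each residue in at most one pair."""

    length: int
    pairs: frozenset[Pair]
    sequence: str | None = None

    def __post_init__(self) -> None:
        seen: set[int] = set()
        for i, j in self.pairs:
            if not (1 <= i < j <= self.length):
                raise StructureFormatError(
                    f"pair ({i},{j}) out of range for length {self.length}"
                )
            if i in seen or j in seen:
                raise StructureFormatError(
                    f"residue in pair ({i},{j}) is paired twice"
                )
            seen.update((i, j))
        if self.sequence is not None and len(self.sequence) != self.length:
            raise StructureFormatError(
                f"sequence length {len(self.sequence)} != structure length "
                f"{self.length}"
            )
        _check_nested(self.pairs)

    def sorted_pairs(self) -> list[Pair]:
        return sorted(self.pairs)


def _check_nested(pairs: frozenset[Pair]) -> None:
    ordered = sorted(pairs)
    for a in range(len(ordered)):
        i, j = ordered[a]
        for b in range(a + 1, len(ordered)):
            k, l = ordered[b]
            if k >= j:
                break
            if k > i and l > j:
                raise PseudoknotError((i, j), (k, l))


# -- parsing -------------------------------------------------------------

_BRACKETS = {"(": ")", "[": "]", "{": "}", "<": ">"}
_CLOSERS = {v: k for k, v in _BRACKETS.items()}


def _parse_dotbracket(text: str) -> SecondaryStructure:
    sequence: str | None = None
    structure: str | None = None
    for raw in text.splitlines():
        line = raw.strip()
        if not line or line.startswith(">") or line.startswith("#"):
            continue
        stripped = line.replace(" ", "")
        if all(c.isalpha() for c in stripped) and sequence is None:
            sequence = stripped.upper().replace("T", "U")
        elif structure is None:
            structure = stripped
        else:
            raise StructureFormatError("more than one structure line")
    if structure is None:
        raise StructureFormatError("no dot-bracket structure line found")
    stacks: dict[str, list[int]] = {b: [] for b in _BRACKETS}
    pairs: set[Pair] = set()
    for pos, c in enumerate(structure, 1):
        if c in _BRACKETS:
            stacks[c].append(pos)
        elif c in _CLOSERS:
            opener = _CLOSERS[c]
            if not stacks[opener]:
                raise StructureFormatError(f"unbalanced {c!r} at position {pos}")
            pairs.add((stacks[opener].pop(), pos))
        elif c in ".-_,:":
            continue
        else:
            raise StructureFormatError(f"unexpected character {c!r} at {pos}")
    for opener, stack in stacks.items():
        if stack:
            raise StructureFormatError(
                f"unbalanced {opener!r} at position {stack[-1]}"
            )
    # higher-order brackets encode crossings; the nesting check names the
    # offending pairs.  Non-crossing non-() brackets are rejected outright.
    if any(c in "[]{}<>" for c in structure):
        _check_nested(frozenset(pairs))
        raise StructureFormatError(
            "dot-bracket input supports '()' brackets only"
        )
    return SecondaryStructure(len(structure), frozenset(pairs), sequence)


def _pairs_from_columns(rows: list[tuple[int, str, int]], what: str) -> SecondaryStructure:
    index = {i: j for i, _, j in rows}
    seq_chars = {i: b for i, b, _ in rows}
    length = max(index) if index else 0
    if sorted(index) != list(range(1, length + 1)):
        raise StructureFormatError(f"{what}: residue indices are not 1..N")
    pairs: set[Pair] = set()
    for i, j in index.items():
        if j == 0:
            continue
        if j not in index or index[j] != i:
            raise StructureFormatError(
                f"{what}: pair columns inconsistent at residue {i} (-> {j})"
            )
        if i < j:
            pairs.add((i, j))
    sequence = "".join(seq_chars[i] for i in range(1, length + 1))
    sequence = sequence.upper().replace("T", "U")
    return SecondaryStructure(length, frozenset(pairs), sequence)


def _parse_ct(text: str) -> SecondaryStructure:
    lines = [
        ln for ln in (raw.split("#", 1)[0].strip() for raw in text.splitlines())
        if ln
    ]
    if not lines:
        raise StructureFormatError("empty CT file")
    header = lines[0].split()
    try:
        declared = int(header[0])
    except (ValueError, IndexError) as exc:
        raise StructureFormatError("CT header must start with the length") from exc
    rows: list[tuple[int, str, int]] = []
    for ln in lines[1:]:
        f = ln.split()
        if len(f) < 6:
            raise StructureFormatError(f"CT row has {len(f)} columns: {ln!r}")
        rows.append((int(f[0]), f[1], int(f[4])))
    if len(rows) != declared:
        raise StructureFormatError(
            f"CT declares {declared} residues but lists {len(rows)}"
        )
    return _pairs_from_columns(rows, "CT")


def _parse_bpseq(text: str) -> SecondaryStructure:
    rows: list[tuple[int, str, int]] = []
    for raw in text.splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        f = line.split()
        if len(f) != 3:
            raise StructureFormatError(f"BPSEQ row needs 3 columns: {raw!r}")
        rows.append((int(f[0]), f[1], int(f[2])))
    if not rows:
        raise StructureFormatError("empty BPSEQ file")
    return _pairs_from_columns(rows, "BPSEQ")


_PARSERS = {
    "dotbracket": _parse_dotbracket,
    "db": _parse_dotbracket,
    "ct": _parse_ct,
    "bpseq": _parse_bpseq,
}


def parse_structure(text: str, format: str = "dotbracket") -> SecondaryStructure:
    """Parse a secondary structure from text in the named dialect."""
    try:
        parser = _PARSERS[format.lower()]
    except KeyError:
        raise StructureFormatError(f"unknown format {format!r}") from None
    return parser(text)


def to_dotbracket(ss: SecondaryStructure) -> str:
    chars = ["."] * ss.length
    for i, j in ss.pairs:
        chars[i - 1] = "("
        chars[j - 1] = ")"
    return "".join(chars)


# -- helices -------------------------------------------------------------


@dataclass(frozen=True)
class Helix:
    """A helical stem: stacked pairs, possibly bridging 1x0 bulges.

    ``pairs`` are ordered outermost first.  ``outer`` and ``inner`` are
    the closing pairs on the exterior and loop sides.
    """

    pairs: tuple[Pair, ...]

    @property
    def outer(self) -> Pair:
        return self.pairs[0]

    @property
    def inner(self) -> Pair:
        return self.pairs[-1]

    def __len__(self) -> int:
        return len(self.pairs)


def _stable_pairs(ss: SecondaryStructure) -> list[Pair]:
    """Annotated pairs minus non-canonical ones (when sequence is known)."""
    if ss.sequence is None:
        return ss.sorted_pairs()
    out = []
    for i, j in ss.sorted_pairs():
        combo = ss.sequence[i - 1] + ss.sequence[j - 1]
        if combo in CANONICAL_PAIRS:
            out.append((i, j))
    return out


def find_helices(ss: SecondaryStructure) -> list[Helix]:
    """Maximal stems, after 1x0-bulge merging and the >1-pair rule.

    Runs of stacked pairs ((i,j),(i+1,j-1),...) are computed first; runs
    separated by exactly one unmatched nucleotide on one strand merge
    into one stem; any resulting stem with a single pair is discarded
    (its residues revert to unpaired status).
    """
    pairs = _stable_pairs(ss)
    pair_set = set(pairs)
    runs: list[list[Pair]] = []
    for p in pairs:
        if (p[0] - 1, p[1] + 1) in pair_set:
            runs[-1].append(p)
        else:
            runs.append([p])
    merged: list[list[Pair]] = []
    for run in runs:
        if merged:
            p, q = merged[-1][-1]
            i, j = run[0]
            gap5 = i - p - 1
            gap3 = q - j - 1
            if gap5 >= 0 and gap3 >= 0 and gap5 + gap3 == 1:
                merged[-1].extend(run)
                continue
        merged.append(run)
    return [Helix(tuple(run)) for run in merged if len(run) >= 2]


# -- elements ------------------------------------------------------------


@dataclass(frozen=True)
class StructuralElement:
    """A vertex-generating single-stranded element."""

    kind: str  # hairpin_loop | internal_or_bulge | junction | exterior
    residues: tuple[int, ...]
    adjacent_helices: tuple[int, ...]  # indices into the helix list
    sort_key: float
    label: int | None = None

    @property
    def residue_ranges(self) -> tuple[tuple[int, int], ...]:
        ranges: list[tuple[int, int]] = []
        for r in self.residues:
            if ranges and r == ranges[-1][1] + 1:
                ranges[-1] = (ranges[-1][0], r)
            else:
                ranges.append((r, r))
        return tuple(ranges)


def _helix_forest(helices: list[Helix]) -> tuple[list[int], dict[int, list[int]]]:
    """Parent links by interval nesting of the outer pairs."""
    order = sorted(range(len(helices)), key=lambda h: helices[h].outer[0])
    children: dict[int, list[int]] = {h: [] for h in range(len(helices))}
    top: list[int] = []
    stack: list[int] = []
    for h in order:
        i, j = helices[h].outer
        while stack and not (
            helices[stack[-1]].outer[0] < i and j < helices[stack[-1]].outer[1]
        ):
            stack.pop()
        if stack:
            children[stack[-1]].append(h)
        else:
            top.append(h)
        stack.append(h)
    return top, children


def classify_elements(
    ss: SecondaryStructure, helices: list[Helix]
) -> list[StructuralElement]:
    """One vertex-generating element per single-stranded region.

    Every helix-loop region (hairpin, internal loop/bulge, junction) and
    the exterior strand becomes exactly one element; elements are
    labeled 1..n in 5'->3' order of their first residue (an element with
    no unpaired residue sorts at the position where it interrupts the
    backbone).
    """
    in_helix = {r for h in helices for p in h.pairs for r in p}
    top, children = _helix_forest(helices)
    elements: list[StructuralElement] = []

    # exterior: everything outside the top-level helix intervals
    covered: set[int] = set()
    for h in top:
        i, j = helices[h].outer
        covered.update(range(i, j + 1))
    ext_res = tuple(r for r in range(1, ss.length + 1) if r not in covered)
    elements.append(
        StructuralElement(
            kind="exterior",
            residues=ext_res,
            adjacent_helices=tuple(sorted(top)),
            sort_key=float(ext_res[0]) if ext_res else 0.0,
        )
    )

    for h, hx in enumerate(helices):
        p, q = hx.inner
        inside: set[int] = set(range(p + 1, q))
        for c in children[h]:
            ci, cj = helices[c].outer
            inside -= set(range(ci, cj + 1))
        residues = tuple(sorted(r for r in inside if r not in in_helix))
        n_child = len(children[h])
        kind = (
            "hairpin_loop" if n_child == 0
            else "internal_or_bulge" if n_child == 1
            else "junction"
        )
        elements.append(
            StructuralElement(
                kind=kind,
                residues=residues,
                adjacent_helices=tuple(sorted([h] + children[h])),
                sort_key=float(residues[0]) if residues else p + 0.5,
            )
        )

    elements.sort(key=lambda e: e.sort_key)
    return [
        StructuralElement(e.kind, e.residues, e.adjacent_helices, e.sort_key, lbl)
        for lbl, e in enumerate(elements, start=1)
    ]


def to_rag_tree(
    ss: SecondaryStructure, name: str | None = None
) -> tuple[RAGTreeGraph, list[StructuralElement]]:
    """Convert a nested structure to its RAG tree graph.

    Returns the graph and the labeled element list (the vertex table).
    Raises :class:`NoHelixError` when no stem with more than one pair
    exists — there is then no graph to build.
    """
    helices = find_helices(ss)
    if not helices:
        raise NoHelixError("structure has no helix with more than one base pair")
    elements = classify_elements(ss, helices)
    by_helix: dict[int, list[int]] = {}
    for e in elements:
        for h in e.adjacent_helices:
            by_helix.setdefault(h, []).append(e.label)
    edges = []
    for h in range(len(helices)):
        ends = by_helix.get(h, [])
        # nesting guarantees each helix separates exactly two elements
        if len(ends) != 2:
            raise AssertionError(
                f"helix {h} is adjacent to {len(ends)} elements; nested "
                "structures always yield trees"
            )
        edges.append((ends[0], ends[1]))
    graph = RAGTreeGraph(
        tuple(range(1, len(elements) + 1)),
        frozenset(tuple(sorted(e)) for e in edges),
        name,
    )
    return graph, elements
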