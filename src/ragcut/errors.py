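"""Exception hierarchy for ragcut.

Validation failures are deliberately fine-grained so callers (and the CLI)
can distinguish a malformed edge list from a structurally invalid tree or
an unsupported secondary structure.
"""


class RagcutError(Exception):
    """Base class for all ragcut errors."""


class GraphValidationError(RagcutError):
    """A putative tree graph violates a structural invariant."""


class SelfLoopError(GraphValidationError):
    pass


class DuplicateEdgeError(GraphValidationError):
    pass


class LabelRangeError(GraphValidationError):
    pass


class CycleError(GraphValidationError):
    pass


class DisconnectedError(GraphValidationError):
    pass


class PartitionError(RagcutError):
    """A spectral cut could not be performed as requested."""


class EmptyPartError(PartitionError):
    """The splitting value would leave one side of the bisection empty."""


class MultiCutError(PartitionError):
    """Overlap extraction requires a single cut edge; the cut has several."""


class ReplayError(RagcutError):
    """A recorded bipartition does not apply to any current fragment."""


class AssemblyError(RagcutError):
    """An assembly plan was requested for a tree without shared vertices."""


class CatalogRangeError(RagcutError):
    """The catalog does not cover the requested vertex count."""


class StructureFormatError(RagcutError):
    """A secondary-structure file is malformed."""


class PseudoknotError(StructureFormatError):
    """The structure contains crossing base pairs (pseudoknot).

    Tree-graph conversion is defined for nested (pseudoknot-free)
    structures only; crossing pairs are a hard error, never silently
    broken.
    """

    def __init__(self, pair_a, pair_b):
        self.pair_a = tuple(pair_a)
        self.pair_b = tuple(pair_b)
        super().__init__(
            f"crossing base pairs {self.pair_a} and {self.pair_b}: "
            "pseudoknotted structures are not representable as tree graphs"
        )


class NoHelixError(StructureFormatError):
    """The structure contains no helix (>1 stacked pair), so no graph exists."""
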