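"""Exception hierarchy for airrtoolkit.

All toolkit-specific failures derive from :class:`AirrToolkitError` so callers
can catch one base class at pipeline boundaries.
"""


class AirrToolkitError(Exception):
    """Base class for all airrtoolkit errors."""


class UnknownFormat(AirrToolkitError):
    """No dialect signature matched the input header."""


class AmbiguousFormat(AirrToolkitError):
    """Two or more dialect signatures tied at the maximum match score."""


class SchemaError(AirrToolkitError):
    """A required column is missing after the format was asserted."""


class EmptyExport(AirrToolkitError):
    """Nothing to export for the requested style."""


class MixedReceptorError(AirrToolkitError):
    """TCR and BCR chains mixed where a single receptor type is required."""


class EmptyRepertoire(AirrToolkitError):
    """No cells survive filtering."""


class UnknownColumn(AirrToolkitError):
    """A metadata column named by the caller does not exist."""


class EmptyInput(AirrToolkitError):
    """An operation received no usable sequences."""


class InvalidCounts(AirrToolkitError):
    """Clone count vector contains zero or negative entries."""


class GroupTooSmall(AirrToolkitError):
    """A group is smaller than the requested downsampling size."""


class InvalidOrder(AirrToolkitError):
    """Hill order q outside {0, 1, 2}."""


class GridOutOfRange(AirrToolkitError):
    """Rarefaction grid point outside [1, endpoint]."""


class MissingLabel(AirrToolkitError):
    """A required per-cell label (clone/cluster/tissue) is missing."""


class DegenerateGroup(AirrToolkitError):
    """A group has zero cells where counts are required."""


class CloneNotFound(AirrToolkitError):
    """An explicitly requested clone is absent from every group."""


class EmptySequence(AirrToolkitError):
    """Similarity requested on an empty string."""


class KTooLarge(AirrToolkitError):
    """No sequence is long enough for the requested k-mer size."""


class UnknownResidue(AirrToolkitError):
    """A residue without physicochemical constants (strict mode only)."""


class DuplicateBarcode(AirrToolkitError):
    """Cell barcode list contains duplicates."""


class InfeasibleSpec(AirrToolkitError):
    """Simulation parameters are mutually inconsistent."""


class UnsupportedDialect(AirrToolkitError):
    """Requested output dialect is not supported."""
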