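"""Exception hierarchy for the pipeline.

Every error a stage can raise derives from :class:`EvorateError` so callers
(and the CLI) can distinguish user-input problems from internal bugs.
"""


class EvorateError(Exception):
    """Base class for all pipeline errors."""


class AlphabetError(EvorateError):
    """A residue outside the amino-acid alphabet (20 letters, '-', 'X')."""


class AlignmentFormatError(EvorateError):
    """Sequences in an alignment do not all share the same length."""


class DuplicateTaxonError(EvorateError):
    """The same taxon name occurs twice where uniqueness is required."""


class ConcatenationError(EvorateError):
    """Locus concatenation produced an empty or inconsistent supermatrix."""


class TimeTreeError(EvorateError):
    """A species time tree is malformed or not ultrametric."""


class IncomparablePairError(EvorateError):
    """A sequence pair shares no comparable (non-gap) columns."""


class SaturationError(EvorateError):
    """A corrected distance is undefined (p-distance at or above 1)."""


class IncompleteMatrixError(EvorateError):
    """A distance matrix with missing entries was passed where completeness
    is required (e.g. neighbor-joining)."""


class NormalizationError(EvorateError):
    """Divergence-time normalization requested with a non-positive time."""


class CoverageError(EvorateError):
    """Taxa in the distance matrix are missing from the tree or clade map."""


class EmptyGroupError(EvorateError):
    """A clade-pair selection matched no pairwise records."""


class DegreesOfFreedomError(EvorateError):
    """Too few values per group for the requested statistical test."""


class BootstrapFailureError(EvorateError):
    """More than the tolerated fraction of bootstrap replicates failed."""


class ConfigError(EvorateError):
    """Invalid simulation or run configuration."""
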