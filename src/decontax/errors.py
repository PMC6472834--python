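"""Exception hierarchy shared across the package."""


class DecontaxError(Exception):
    """Base class for all package errors."""


class ParseError(DecontaxError):
    """A malformed record in an input file (message names file and line)."""


class StructuralError(DecontaxError):
    """Inconsistent taxonomy structure (unknown parent, broken lineage)."""


class UnknownTaxonError(DecontaxError):
    """A taxid that cannot be resolved, even through merged.dmp."""


class RankOrderError(DecontaxError):
    """Rank comparison involving the NO_RANK sentinel or an unknown label."""


class DegenerateSampleError(DecontaxError):
    """A sample with no usable reads at the requested stage."""


class UsageError(DecontaxError):
    """Invalid combination of arguments or configuration."""


class PairingError(DecontaxError):
    """Mate files out of sync during paired-end read extraction."""


class DesignError(DecontaxError):
    """A mock design referencing taxa absent from the taxonomy or malformed."""


class EvaluationError(DecontaxError):
    """A result taxon that the truth table does not cover."""
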