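"""Typed exceptions shared across the package."""


class ImgFPCError(Exception):
    """Base class for all package errors."""


class InvalidArgumentError(ImgFPCError, ValueError):
    """A parameter is outside its documented range."""


class CohortInconsistencyError(ImgFPCError, ValueError):
    """Images in a cohort do not share a common pixel grid."""


class IdentifiabilityError(ImgFPCError, ValueError):
    """The basis has more coefficients than the grid has pixels."""


class DegenerateCohortError(ImgFPCError, ValueError):
    """The cohort is too small for the requested operation."""


class ContractViolationError(ImgFPCError, ValueError):
    """An input violates a precondition of the calling operation."""


class RankDeficiencyError(ImgFPCError, ValueError):
    """A sketch or data matrix has lower numerical rank than required."""


class DegeneratePartitionError(ImgFPCError, ValueError):
    """A clustering has an empty cluster."""


class DegenerateInputError(ImgFPCError, ValueError):
    """Input data are degenerate (e.g. all rows identical)."""


class SizeLimitError(ImgFPCError, ValueError):
    """A brute-force computation was requested beyond its size limit."""
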