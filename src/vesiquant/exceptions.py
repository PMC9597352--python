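"""Exception hierarchy.

Degenerate inputs raise rather than silently returning 0/NaN, so a caller
can distinguish "no signal" from "signal of zero".
"""


class VesiquantError(Exception):
    """Base class for all package errors."""


class InvalidArgumentError(VesiquantError, ValueError):
    """An argument violates a documented precondition."""


class DegenerateFitError(VesiquantError):
    """Too few usable points to fit (e.g. a motionless track's MSD)."""


class DegenerateInputError(VesiquantError):
    """Input has no usable variation (e.g. constant image, zero variance)."""


class UndefinedResultError(VesiquantError):
    """The requested quantity is mathematically undefined for this input
    (e.g. a Manders denominator with no supra-threshold signal)."""


class EmptyResultError(VesiquantError):
    """A summary was requested over an empty collection."""


class GenerationError(VesiquantError):
    """A synthetic-data placement could not be satisfied within bounded
    retries."""
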