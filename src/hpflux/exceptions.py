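"""Exception hierarchy for hpflux.

Every error raised by the package derives from :class:`HpfluxError` so that
callers can catch pipeline failures with a single except clause while still
letting programming errors (TypeError etc.) propagate.
"""


class HpfluxError(Exception):
    """Base class for all hpflux errors."""


class InvalidParameterError(HpfluxError, ValueError):
    """A numeric parameter is out of its physical/valid range."""


class EmptyInputError(HpfluxError, ValueError):
    """An operation received an empty array or list."""


class EmptyWindowError(HpfluxError, ValueError):
    """A time/frequency window contains no usable points."""


class InvalidWindowError(HpfluxError, ValueError):
    """A requested window does not fit inside the available axis."""


class GeometryError(HpfluxError, ValueError):
    """Phantom geometry is inconsistent (e.g. tumor outside brain)."""


class ShapeError(HpfluxError, ValueError):
    """Array dimensions do not match the declared acquisition geometry."""


class EmptyRoiError(HpfluxError, ValueError):
    """A region-of-interest mask selects no voxels."""


class EmptyCohortError(HpfluxError, ValueError):
    """A cohort specification yields zero animals."""


class RangeError(HpfluxError, ValueError):
    """A spectral window lies outside the frequency axis."""


class UndefinedGrowthError(HpfluxError, ValueError):
    """Growth rate requested with a non-positive baseline volume."""


class EmptySampleError(HpfluxError, ValueError):
    """A statistical routine received an empty sample."""


class UndefinedCorrelationError(HpfluxError, ValueError):
    """Correlation requested on constant or too-short input."""


class SchemaError(HpfluxError, ValueError):
    """A file does not conform to the declared on-disk schema."""
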