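"""Exception hierarchy for saxsqc.

Every anticipated failure mode raises a subclass of :class:`SaxsQCError`
so callers (and the CLI) can distinguish bad input from bugs.
"""


class SaxsQCError(Exception):
    """Base class for all saxsqc errors."""


class InvalidGeometryError(SaxsQCError):
    """Detector geometry with non-positive wavelength/distance/pixel size."""


class GridMismatchError(SaxsQCError):
    """Two profiles whose q grids do not match where they must."""


class RangeError(SaxsQCError):
    """A requested q window falls outside the coverage of a profile."""


class EmptySliceError(SaxsQCError):
    """An azimuthal slice that contains no usable pixels in any q bin."""


class DomainError(SaxsQCError):
    """An argument outside its documented domain."""


class DegenerateComparisonError(SaxsQCError):
    """A profile comparison with no informative (non-tied) points."""


class InsufficientDataError(SaxsQCError):
    """Too few usable q points to run a center scan."""


class DegenerateBufferError(SaxsQCError):
    """A buffer profile whose water-peak magnitude is not positive."""


class StartInfeasibleError(SaxsQCError):
    """Scaling-factor search whose criteria already fail at the start factor.

    A factor below the starting value signals a pathological sample/buffer
    pair that needs human attention rather than automation.
    """


class ValidationError(SaxsQCError):
    """A spreadsheet failed validation (carries the report)."""

    def __init__(self, report, message="sheet failed validation"):
        super().__init__(message)
        self.report = report


class CapacityError(SaxsQCError):
    """A plan that exceeds a hard capacity (deck slots, holder storage)."""

    def __init__(self, message, suggestion=None):
        super().__init__(message)
        self.suggestion = suggestion


class UnknownHolderError(SaxsQCError):
    """A holder UUID with no registered sample information."""


class FormatError(SaxsQCError):
    """A malformed identifier (proposal / SAF / plate id / payload)."""
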