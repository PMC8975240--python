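"""Exception hierarchy.

Everything raised on bad *values* derives from ``ValueError`` so callers can
catch broadly; geometry/IO failures get their own branches.
"""


class ThermogradError(Exception):
    """Base class for all package-specific errors."""


class DomainError(ThermogradError, ValueError):
    """An input value is outside the physical or mathematical domain."""


class UnsupportedModeError(ThermogradError, ValueError):
    """A radiometric frame is not in a convertible mode (TLinear disabled)."""


class BoundsError(ThermogradError, ValueError):
    """A point or window falls outside the image extent."""


class GeometryError(ThermogradError, ValueError):
    """A geometric construction is invalid (short polyline, patch off-body...)."""


class InsufficientDataError(ThermogradError, ValueError):
    """Too few observations to carry out the operation."""


class DegenerateGeometryError(ThermogradError, ValueError):
    """A point configuration is rank-deficient (e.g. all collinear)."""


class SingularTransformError(ThermogradError, ValueError):
    """A planar transform is not invertible."""


class BoardDetectionError(ThermogradError, RuntimeError):
    """Checkerboard corner detection failed; the message names the shortfall."""


class UndefinedCorrelationError(ThermogradError, ValueError):
    """Correlation is undefined (constant input vector)."""


class ValidationError(ThermogradError, ValueError):
    """A CSV/JSON input failed schema validation; message names row/field."""
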