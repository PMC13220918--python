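"""Exception hierarchy.

All package errors derive from :class:`FlimError` so callers can catch one
base class. Sub-hierarchies distinguish configuration problems (bad options,
caught before any computation), data problems (malformed or invalid inputs)
and numerical failures (well-posed inputs on which the algorithm degenerates).
"""


class FlimError(Exception):
    """Base class for all errors raised by flimlite."""


class ConfigurationError(FlimError):
    """An option set or config file is incomplete or inconsistent."""


class FormatError(FlimError):
    """A file does not conform to the expected on-disk format."""


class ValidationError(FlimError, ValueError):
    """An in-memory object or argument violates a documented precondition."""


class SaturationError(ValidationError):
    """Pile-up correction requested on counts at or beyond the frame count."""


class EmptyDecayError(ValidationError):
    """A decay with zero total counts where a phasor or fit needs signal."""


class NumericalError(FlimError):
    """A computation degenerated (no solution, singular geometry, ...)."""


class DegenerateCalibrationError(NumericalError):
    """Calibration phasor has (near-)zero modulus; division undefined."""


class DegenerateAxisError(NumericalError):
    """Phasor cloud is isotropic: principal axes are not distinguishable."""


class NoIntersectionError(NumericalError):
    """The principal axis does not cross the universal circle."""


class TangencyError(NoIntersectionError):
    """The principal axis touches the universal circle at a single point.

    Carries the tangent point so callers can inspect the degenerate pair.
    """

    def __init__(self, message: str, point=None):
        super().__init__(message)
        self.point = point


class NotOnCircleError(ValidationError):
    """A phasor assumed to lie on the universal circle is too far off it."""
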