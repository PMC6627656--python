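"""Exception hierarchy for radusm.

All library errors derive from :class:`RadusmError` so callers can catch the
whole family with one clause; most also derive from ``ValueError`` because
they signal invalid arguments rather than environmental failures.
"""


class RadusmError(Exception):
    """Base class for all radusm errors."""


class FormatError(RadusmError, ValueError):
    """An image file or byte stream is not in the expected format."""


class RangeError(RadusmError, ValueError):
    """Pixel intensities fall outside the range a writer can encode."""


class DimensionError(RadusmError, ValueError):
    """Grids passed to an operation do not have compatible shapes."""


class ParameterError(RadusmError, ValueError):
    """A numeric parameter violates its documented constraint."""


class StabilityError(RadusmError, ValueError):
    """An explicit time step exceeds its stability bound."""


class PhantomSpecError(RadusmError, ValueError):
    """A phantom specification cannot be rendered (e.g. a tube leaves the image)."""


class UndefinedSNRError(RadusmError, ValueError):
    """SNR is undefined because the noise region has zero standard deviation."""


class BreakdownError(RadusmError, RuntimeError):
    """The bi-conjugate gradient recurrence broke down (a division by ~0)."""

    def __init__(self, message: str, iteration: int):
        super().__init__(message)
        self.iteration = iteration


class ConvergenceError(RadusmError, RuntimeError):
    """An iterative solve failed to reach its tolerance within its budget."""

    def __init__(self, message: str, residual_history=None):
        super().__init__(message)
        self.residual_history = list(residual_history or [])
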