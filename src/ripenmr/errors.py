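"""Exception hierarchy shared across the pipeline."""


class RipenmrError(Exception):
    """Base class for all package-specific errors."""


class InvalidSchemeError(RipenmrError, ValueError):
    """Acquisition scheme parameters are inconsistent or out of range."""


class GridError(RipenmrError, ValueError):
    """A relaxation/diffusion grid is malformed (non-positive values, too few points)."""


class DomainError(RipenmrError, ValueError):
    """A physical quantity is outside its admissible domain (e.g. negative D)."""


class DegenerateInputError(RipenmrError, ValueError):
    """Input carries no usable signal (all-zero series, zero-amplitude mixture)."""


class ConvergenceError(RipenmrError, RuntimeError):
    """Iterative solver failed to converge; carries the last iterate."""

    def __init__(self, message, last_iterate=None):
        super().__init__(message)
        self.last_iterate = last_iterate


class CompressionError(RipenmrError, RuntimeError):
    """SVD kernel compression left too little rank to invert."""


class FitError(RipenmrError, RuntimeError):
    """Peak fit window is degenerate (fewer points than parameters)."""


class ParseError(RipenmrError, ValueError):
    """A dataset/map file is malformed; the message names the offending field."""


class RangeError(RipenmrError, KeyError):
    """Requested day/depth is not covered by the scenario or series."""
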