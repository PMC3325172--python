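"""Exception hierarchy.

Validation failures (bad parameters, malformed input) map to CLI exit
code 2, numerical failures (quadrature, non-convergence) to exit code 3.
"""


class IsilawError(Exception):
    """Base class for all package errors."""


class ValidationError(IsilawError, ValueError):
    """Invalid parameter or malformed input data."""


class DegenerateInputError(ValidationError):
    """Input is formally valid but carries no usable signal
    (e.g. all inter-spike intervals fall outside the histogram range)."""


class MomentsUndefinedError(ValidationError):
    """A requested moment does not exist for the given tail shape."""


class InsufficientTailError(IsilawError):
    """Too few usable bins beyond the fit-range cutoff to regress a tail."""


class NumericError(IsilawError, RuntimeError):
    """Quadrature or optimisation failure."""
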