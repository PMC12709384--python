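"""Exception hierarchy.

``ValidationError`` covers malformed or out-of-contract inputs,
``InsufficientDataError`` too few data for the requested operation,
``NumericalError`` degeneracies discovered while solving (singular kriging
systems, non-positive-definite covariances).  The CLI maps these to exit
codes 2 (validation) and 3 (numerical).
"""


class FrapMapError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(FrapMapError, ValueError):
    pass


class InsufficientDataError(ValidationError):
    pass


class NumericalError(FrapMapError, ArithmeticError):
    pass
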