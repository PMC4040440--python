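"""Exception hierarchy shared across the package."""


class GenoprogError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(GenoprogError, ValueError):
    """A parameter or derived quantity violates a model invariant."""


class InputError(GenoprogError, ValueError):
    """An input file cannot be parsed or violates the file contract."""


class ConvergenceError(GenoprogError, RuntimeError):
    """An iterative solver failed to converge."""


class UndefinedMetricError(GenoprogError, ZeroDivisionError):
    """A metric is undefined for the given inputs (zero denominator)."""
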