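"""Exception hierarchy shared across the package."""


class AdsStarError(Exception):
    """Base class for all package errors."""


class ParseError(AdsStarError, ValueError):
    """Malformed input text (event intervals, edge lists, configs)."""


class ValidationError(AdsStarError, ValueError):
    """Structurally valid input that violates a contract."""


class ConvergenceError(AdsStarError, RuntimeError):
    """Iterative fitting failed to converge; carries the iteration trace."""

    def __init__(self, message: str, trace=None):
        super().__init__(message)
        self.trace = trace if trace is not None else []


class DependencyError(AdsStarError, RuntimeError):
    """A pipeline stage was invoked before its upstream artifacts exist."""
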