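"""Exception hierarchy shared across the package.

Exit-code mapping used by the CLI: :class:`ParseError` and
:class:`DomainError` are usage errors (exit 1); :class:`IntegrityError`
signals a verification mismatch (exit 2).
"""


class OrbitcountError(Exception):
    """Base class for all package-specific errors."""


class DomainError(OrbitcountError, ValueError):
    """An argument is outside its documented domain (bad id, mask, parameter)."""


class PreconditionError(OrbitcountError, ValueError):
    """An operation's precondition does not hold (e.g. ADD of an existing edge)."""


class StreamError(PreconditionError):
    """A modification stream violates a precondition at a specific step."""

    def __init__(self, index: int, message: str):
        super().__init__(f"step {index}: {message}")
        self.index = index


class ParseError(OrbitcountError, ValueError):
    """A text input could not be parsed; carries the 1-based line number."""

    def __init__(self, line: int, message: str):
        super().__init__(f"line {line}: {message}")
        self.line = line


class IntegrityError(OrbitcountError, RuntimeError):
    """Two computation routes that must agree did not."""


class UndefinedMetricError(OrbitcountError, ValueError):
    """An evaluation metric is undefined for the given inputs."""
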