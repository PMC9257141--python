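"""Exception hierarchy shared across the package."""


class MemneuroError(Exception):
    """Base class for package errors."""


class ParameterError(MemneuroError, ValueError):
    """A parameter violates its documented precondition."""


class DomainError(MemneuroError, ValueError):
    """An input lies outside the mathematical domain of an operation."""


class ConfigError(MemneuroError, ValueError):
    """A run configuration failed schema validation."""


class NumericalError(MemneuroError, ArithmeticError):
    """A simulation produced non-finite state (blow-up)."""
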