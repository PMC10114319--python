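"""Typed exceptions shared across the package."""


class PericfdnaError(Exception):
    """Base class for all package errors."""


class ValidationError(PericfdnaError, ValueError):
    """A record or parameter violates a domain invariant."""


class SchemaError(PericfdnaError, ValueError):
    """A table on disk is missing required columns or is otherwise malformed."""


class UndefinedStatisticError(PericfdnaError, ArithmeticError):
    """A statistic is undefined for the given input (e.g. zero denominator,
    degenerate marginals) and must not be silently reported as a number."""


class PipelineError(PericfdnaError, RuntimeError):
    """A pipeline stage failed; the message names the stage."""
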