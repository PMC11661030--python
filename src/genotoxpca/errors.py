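"""Exception hierarchy for the pipeline.

Every stage raises a subclass of :class:`GenotoxError` so callers (and the
CLI) can distinguish pipeline failures from programming errors.
"""


class GenotoxError(Exception):
    """Base class for all package errors."""


class FormatError(GenotoxError):
    """A file does not have the expected tabular layout."""


class IntegrityError(GenotoxError):
    """A table violates a uniqueness or completeness invariant."""


class DomainError(GenotoxError):
    """A value is outside the domain an operation is defined on."""


class DesignError(GenotoxError):
    """The study design is incomplete (e.g. a missing control group)."""


class DegenerateInputError(DomainError):
    """Input is formally valid but numerically degenerate (zero variance)."""


class ConfigError(GenotoxError):
    """A run or simulation configuration is invalid."""
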