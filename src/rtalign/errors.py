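"""Exception hierarchy.

User-facing errors (bad config, bad input files, nothing left to align)
derive from :class:`UserError` so the CLI can map them to exit code 1;
everything else is treated as an internal error (exit code 2).
"""


class RTAlignError(Exception):
    """Base class for all package errors."""


class UserError(RTAlignError):
    """Errors caused by user input: config, file contents, infeasible settings."""


class ConfigurationError(UserError):
    """Invalid or incomplete configuration (missing column, unknown key, ...)."""


class EmptyInputError(UserError):
    """An input table contained no rows."""


class InvalidRecordError(UserError):
    """A single record violates a basic invariant (e.g. empty peptide sequence)."""


class NoAlignableDataError(UserError):
    """Every PSM was removed by the alignment-eligibility filters."""


class NumericalError(RTAlignError):
    """Degenerate numerical configuration (zero slope, non-finite density)."""
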