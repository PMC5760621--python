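"""Exception hierarchy.

User-facing errors split into two classes so the CLI can map them to
distinct exit codes: configuration/usage problems vs. malformed input data.
"""


class SigtargetError(Exception):
    """Base class for all package errors."""


class ConfigurationError(SigtargetError):
    """A parameter, option, or dataset layout violates a precondition."""


class InputError(SigtargetError):
    """Input data is malformed (non-finite values, unknown entities, ...)."""


class UndefinedCorrelationError(SigtargetError):
    """Correlation requested on a constant vector."""
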