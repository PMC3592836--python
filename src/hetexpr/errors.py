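"""Exception hierarchy.

``ConfigError`` marks an invalid configuration value (the message names the
offending field); ``ContractViolation`` marks data that breaks an operation's
precondition; ``DataError`` marks malformed or inconsistent input files.
"""


class HetexprError(Exception):
    """Base class for all package errors."""


class ConfigError(HetexprError, ValueError):
    """An invalid configuration value; the message names the field."""


class ContractViolation(HetexprError, ValueError):
    """Input violates an operation's stated precondition."""


class DataError(HetexprError, ValueError):
    """Malformed or internally inconsistent input data."""
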