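"""Exception hierarchy for mpaconnect."""


class MPAConnectError(Exception):
    """Base class for all package errors."""


class ValidationError(MPAConnectError, ValueError):
    """An input value violates a documented precondition."""


class ConfigurationError(MPAConnectError):
    """An experiment or scenario configuration is inconsistent."""


class FieldCoverageError(ConfigurationError):
    """The ocean field does not cover the time span a simulation needs."""


class IntegrityError(MPAConnectError):
    """An internal consistency invariant was violated (e.g. overlapping sites)."""


class ParseError(MPAConnectError):
    """A file could not be interpreted; the message names what is missing."""
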