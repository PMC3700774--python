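"""Exception hierarchy.

``InputError`` covers anything wrong with user-supplied files or
configuration (CLI exit code 2); ``StageError`` covers failures of an
analysis stage on otherwise valid input (CLI exit code 3).
"""


class CiliaMotionError(Exception):
    """Base class for all package errors."""


class InputError(CiliaMotionError):
    """Invalid configuration, file, or argument supplied by the user."""


class ConfigError(InputError):
    """A configuration value violates a documented invariant."""


class MovieParseError(InputError):
    """A movie file could not be decoded; names the offending frame."""


class StageError(CiliaMotionError):
    """An analysis stage failed on structurally valid input."""


class InsufficientMotionError(StageError):
    """The movie shows too little angular motion to fit an arc path."""


class TraceUnreliableError(StageError):
    """Too many frames lacked signal for a trustworthy tip-angle trace."""
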