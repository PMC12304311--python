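"""Exception hierarchy.

``InputError`` marks problems with user-supplied data or configuration
(CLI exit code 2); ``ComputationError`` marks failures arising during an
otherwise valid run (exit code 3).
"""


class StatepopError(Exception):
    """Base class for all package errors."""


class InputError(StatepopError, ValueError):
    """Invalid input data, file, or configuration."""


class ComputationError(StatepopError, RuntimeError):
    """A computation could not be completed on valid input."""
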