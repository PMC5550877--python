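"""Exception hierarchy.

Input/configuration problems and statistical preconditions are kept apart so
the CLI can map them onto distinct exit codes (2 and 3 respectively).
"""


class DifnetError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class InputError(DifnetError):
    """Malformed or inconsistent user input."""

    exit_code = 2


class ConfigurationError(InputError):
    """A configuration value violates a documented bound."""


class ParseError(InputError):
    """A file could not be parsed; the message names the offending line."""


class StatisticsError(DifnetError):
    """A statistical precondition (e.g. minimum sample size) is not met."""

    exit_code = 3


class PipelineError(DifnetError):
    """A pipeline stage failed; the message names the stage."""
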