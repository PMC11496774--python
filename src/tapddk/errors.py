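"""Exception hierarchy shared across the package.

Every error a pipeline stage can raise derives from :class:`TapDDKError`,
so callers (and the CLI) can distinguish domain validation failures from
programming errors.
"""


class TapDDKError(Exception):
    """Base class for all domain errors."""


class StreamValidationError(TapDDKError):
    """An input stream violates a structural invariant (names the field)."""


class DegenerateSignalError(TapDDKError):
    """Signal carries no usable oscillation (e.g. constant displacement)."""


class TooShortError(TapDDKError):
    """Recording is too short for the requested analysis."""


class InsufficientDataError(TapDDKError):
    """Not enough paired observations for an agreement statistic."""


class FormatError(TapDDKError):
    """A file on disk does not match the expected dialect."""
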