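"""Error types shared across the pipeline."""


class SpecEventsError(Exception):
    """Base class for all package errors."""


class InvalidArgumentError(SpecEventsError, ValueError):
    """An argument violates a documented precondition."""


class EmptyInputError(InvalidArgumentError):
    """An operation received no usable data."""


class DegenerateInputError(InvalidArgumentError):
    """Input is formally valid but numerically degenerate (e.g. zero median)."""


class FormatError(SpecEventsError, ValueError):
    """A file could not be parsed as the declared format."""
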