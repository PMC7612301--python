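"""Exception hierarchy for the pipeline.

The CLI maps ValidationError to exit code 2 and ProcessingError to 3.
"""


class IeegStimError(Exception):
    """Base class for all package errors."""


class ValidationError(IeegStimError, ValueError):
    """Invalid configuration, malformed input, or broken invariant."""


class SchedulingError(ValidationError):
    """A synthetic session timeline cannot be realised within its limits."""


class FormatError(IeegStimError):
    """An on-disk artefact could not be parsed."""


class ProcessingError(IeegStimError):
    """A pipeline stage failed on valid inputs (e.g. too few usable channels)."""
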