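"""Exception hierarchy shared across the pipeline stages."""


class SleepSpecError(Exception):
    """Base class for all errors raised by sleepspec."""


class FormatError(SleepSpecError):
    """A file could not be parsed as the expected on-disk format."""


class ValidationError(SleepSpecError):
    """Input values violate a documented invariant or precondition."""


class ChannelLookupError(SleepSpecError):
    """A requested channel / device key is not available."""


class AlignmentError(ValidationError):
    """Subject identifiers do not line up across input tables."""


class ProcessingError(SleepSpecError):
    """A computation could not proceed (e.g. no eligible data windows)."""
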