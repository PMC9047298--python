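"""Exception hierarchy shared across the pipeline."""


class SquealkitError(Exception):
    """Base class for all squealkit errors."""


class FormatError(SquealkitError):
    """Unreadable or unsupported audio file."""


class DegenerateSignalError(SquealkitError):
    """Signal or spectrum carries no energy; the operation is undefined."""


class InsufficientSamplesError(SquealkitError):
    """Clip is too short for the requested windowing or analysis."""


class BoundsError(SquealkitError):
    """Segment bounds are outside the clip or inverted."""
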