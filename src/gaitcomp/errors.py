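"""Exception hierarchy shared across the pipeline stages."""


class GaitCompError(Exception):
    """Base class for all package errors."""


class ParseError(GaitCompError):
    """A file could not be parsed; the message names the offending record."""


class SchemaError(GaitCompError):
    """A file parses but violates the documented schema."""


class ValidationError(GaitCompError):
    """A value violates a domain invariant."""


class ParameterError(GaitCompError):
    """A caller-supplied parameter is out of its documented range."""


class UnrecoverableSequenceError(GaitCompError):
    """Too few valid anchor frames to repair a pose sequence."""


class DegenerateDataError(GaitCompError):
    """Input is too small or degenerate for the requested statistic."""


class EmptyAfterFilterError(GaitCompError):
    """Outlier filtering removed every entry; the message names the threshold."""
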