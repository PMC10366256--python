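"""Exception hierarchy for majorload.

All package-specific failures derive from :class:`MajorLoadError` so callers
can catch one base class at the CLI boundary.
"""


class MajorLoadError(Exception):
    """Base class for all majorload errors."""


class SchemaError(MajorLoadError):
    """An input table is missing required columns or has the wrong layout."""


class ParseError(MajorLoadError):
    """A row of an input table could not be parsed; the message names the line."""


class EmptyDatasetError(MajorLoadError):
    """An operation that needs at least one sample received none."""


class DegenerateVectorError(MajorLoadError):
    """A zero (or numerically zero) vector where a direction is required."""


class CoverageViolationError(MajorLoadError):
    """A sample that must be covered by at least one cone is not."""


class InstanceTooLargeError(MajorLoadError):
    """The exact set-cover oracle was asked for an instance beyond its bound."""
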