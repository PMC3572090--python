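"""Exception hierarchy for isoscope."""


class IsoscopeError(Exception):
    """Base class for all isoscope errors."""


class AlignmentError(IsoscopeError):
    """Sequences in one dataset do not share a common alignment length."""


class MappingError(IsoscopeError):
    """A sample present in the sequence file is missing from the population map."""


class AlphabetError(IsoscopeError):
    """A sequence contains a character outside the declared alphabet."""


class ParseError(IsoscopeError):
    """A tabular input cell could not be parsed (e.g. non-integer repeat count)."""


class ShapeError(IsoscopeError):
    """A tabular input row has the wrong number of fields."""


class EmptyDatasetError(IsoscopeError):
    """A dataset with zero records where at least one is required."""


class ConfigError(IsoscopeError):
    """A scenario configuration file is missing a required key."""


class ValidationError(IsoscopeError):
    """A value violates a model or prior-range invariant."""


class UndefinedStatisticError(IsoscopeError):
    """The requested statistic is undefined for this input (e.g. n < 2)."""


class DegenerateGroupError(IsoscopeError):
    """A population has too few members for a grouped analysis."""
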