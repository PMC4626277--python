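"""Exception hierarchy shared across modules."""


class ChaptrajError(Exception):
    """Base class for all package errors."""


class FormatError(ChaptrajError):
    """A file does not parse under its declared format."""


class EmptyInputError(ChaptrajError):
    """An input resolved to zero atoms / frames / records."""


class TopologyError(ChaptrajError):
    """Trajectory and topology disagree (e.g. atom counts)."""


class SelectionError(ChaptrajError):
    """A selection is invalid, empty, or overlaps where it must not."""


class ThresholdError(ChaptrajError):
    """Threshold parameters violate their ordering constraints."""


class ConfigurationError(ChaptrajError):
    """Missing or inconsistent configuration (e.g. PBC requested, no box)."""


class StructureError(ChaptrajError):
    """Required atoms are missing from a structure."""


class DegenerateInputError(ChaptrajError):
    """Well-formed input on which the statistic is undefined."""


class ParameterError(ChaptrajError):
    """A numeric/categorical parameter is out of its valid domain."""


class RangeError(ChaptrajError):
    """A query lies outside the supported span (grids, windows)."""


class IntegrationError(ChaptrajError):
    """Numerical integration diverged; a smaller step is required."""
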