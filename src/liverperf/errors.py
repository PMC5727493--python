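"""Exception hierarchy shared across the package."""


class LiverPerfError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(LiverPerfError, ValueError):
    """A kinetic or configuration parameter violates its physical constraints."""


class InvalidArgumentError(LiverPerfError, ValueError):
    """An operation argument is outside its admissible range."""


class GridMismatchError(LiverPerfError, ValueError):
    """Curves or volumes that must share a time grid do not."""


class FormatError(LiverPerfError, ValueError):
    """An input file does not conform to the expected on-disk format."""


class MaskError(LiverPerfError, ValueError):
    """A region-of-interest mask is empty or inconsistent with its volume."""


class SpecificationError(LiverPerfError, ValueError):
    """A synthetic-cohort specification is infeasible (e.g. mean far outside bounds)."""
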