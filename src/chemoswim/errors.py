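"""Exception hierarchy used across the package."""


class ChemoswimError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(ChemoswimError, ValueError):
    """A physical parameter is outside its admissible range."""


class GeometryError(ChemoswimError, ValueError):
    """A geometric specification is degenerate or inconsistent."""


class StepSizeError(ChemoswimError, ValueError):
    """The integration step is too coarse for the rotational timescale."""


class FitError(ChemoswimError, RuntimeError):
    """A model fit cannot be performed on the supplied data."""


class DataError(ChemoswimError, ValueError):
    """Input data violate a structural requirement."""


class InsufficientDataError(DataError):
    """Not enough tracks / points to compute the requested statistic."""
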