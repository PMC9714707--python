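"""Exception hierarchy shared across the package."""


class EpirobustError(Exception):
    """Base class for all errors raised by this package."""


class InvalidParameterError(EpirobustError, ValueError):
    """A parameter is outside its admissible range."""


class DegenerateSeriesError(EpirobustError):
    """A series is degenerate for the requested computation (e.g. constant
    after detrending, zero spectral variance)."""


class DegenerateDesignError(EpirobustError):
    """A regression design matrix is rank deficient (e.g. constant regressor)."""


class InsufficientDataError(EpirobustError):
    """Not enough observations to carry out the requested computation."""
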