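"""Exception hierarchy shared across the package."""


class SeizureQdError(Exception):
    """Base class for package-specific failures."""


class DataError(SeizureQdError):
    """Raised when input data are malformed (NaNs, non-finite matrices, ...)."""


class FitError(SeizureQdError):
    """Raised when a model fit fails to converge or the design is degenerate."""


class SimulationError(SeizureQdError):
    """Raised when a simulation leaves its declared safe operating range."""
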