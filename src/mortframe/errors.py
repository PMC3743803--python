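"""Exception types shared across the pipeline stages."""


class MortframeError(Exception):
    """Base class for all package errors."""


class ConfigurationError(MortframeError, ValueError):
    """Invalid generator or pipeline configuration."""


class ParameterError(MortframeError, ValueError):
    """Statistical parameter outside its admissible range."""


class UndefinedStatisticError(MortframeError, ZeroDivisionError):
    """A ratio or proportion whose denominator is zero or degenerate."""


class ModelError(MortframeError, RuntimeError):
    """Model fitting failed (non-convergence, too few clusters, ...)."""
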