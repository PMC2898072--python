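"""Exception hierarchy shared across the pipeline stages."""


class AdnapipeError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(AdnapipeError, ValueError):
    """A rate, probability or size argument is outside its valid range."""


class CoordinateError(AdnapipeError, ValueError):
    """An interval lies outside the genome or alignment it refers to."""


class DegenerateInputError(AdnapipeError, ValueError):
    """Input is structurally valid but carries no usable signal
    (e.g. an alignment with zero ungapped columns)."""


class SamplingExhaustedError(AdnapipeError, RuntimeError):
    """Rejection sampling hit its attempt cap before producing enough
    accepted draws."""


class SizeError(AdnapipeError, ValueError):
    """A dynamic-programming lattice exceeds the configured cap."""


class UndefinedEstimateError(AdnapipeError, ZeroDivisionError):
    """The triangulation denominator (Hs + Cs) is zero."""


class ConfigError(AdnapipeError, ValueError):
    """A run configuration references missing files or invalid stages."""
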