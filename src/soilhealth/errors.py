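"""Exception hierarchy.

Every error raised by this package derives from :class:`SoilHealthError`,
split into configuration/validation problems (bad inputs, caught before any
computation) and numerical/domain problems (raised mid-computation).
"""


class SoilHealthError(Exception):
    """Base class for all package errors."""


class ConfigurationError(SoilHealthError):
    """Invalid configuration value (bad threshold, non-positive mean, ...)."""


class ValidationError(SoilHealthError):
    """Malformed input table: duplicate ids, missing values, non-numeric cells."""


class EmptySampleError(SoilHealthError):
    """Diversity metric requested for an all-zero count vector."""


class UndefinedEstimatorError(SoilHealthError):
    """Richness estimator undefined for this input (e.g. classic Chao1 with F2=0)."""


class SelectionError(SoilHealthError):
    """Candidate selection produced an empty set."""


class ConvergenceError(SoilHealthError):
    """Power iteration failed to converge within the iteration budget."""


class NormalizationError(SoilHealthError):
    """Indicator normalization hit a zero/negative observed or reference value."""


class GeometryError(SoilHealthError):
    """Radar-polygon area requested with fewer than 3 vertices."""


class DomainError(SoilHealthError):
    """Exposure/economics input outside its physical domain."""
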