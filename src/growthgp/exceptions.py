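"""Exception hierarchy for growthgp."""


class GrowthGPError(Exception):
    """Base class for all growthgp errors."""


class ConfigurationError(GrowthGPError):
    """Invalid configuration (unknown covariance family, bad bounds, missing columns...)."""


class UnsupportedSmoothnessError(GrowthGPError):
    """A derivative order was requested that the covariance family cannot support."""


class NumericalConditioningError(GrowthGPError):
    """A covariance matrix could not be factorized even after jitter escalation."""


class OptimizationFailureError(GrowthGPError):
    """Every hyperparameter optimization restart failed numerically."""


class ReplicateCountError(GrowthGPError):
    """Not enough replicates for an operation (e.g. empirical noise estimation)."""


class NoiseEstimationError(GrowthGPError):
    """Degenerate input to the empirical noise estimator (e.g. zero variance everywhere)."""


class ParseError(GrowthGPError):
    """Malformed tabular input."""
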