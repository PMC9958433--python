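"""Exception hierarchy shared across the package."""


class LosRangeError(Exception):
    """Base class for all package errors."""


class ConfigurationError(LosRangeError):
    """Invalid configuration value (bad regime, split fraction, loss id, ...)."""


class EmptyCohortError(LosRangeError):
    """A cohort with zero patients was requested or supplied."""


class ImputationError(LosRangeError):
    """A continuous column has no observed values to impute from."""


class FormatError(LosRangeError):
    """A cohort file violates the expected layout (e.g. missing label column)."""


class ParseError(LosRangeError):
    """A declared-numeric cell failed to parse; message carries row/column."""


class FeatureMismatchError(LosRangeError):
    """Prediction-time columns do not match the training schema."""


class TrainingDivergenceError(LosRangeError):
    """A training loss became non-finite; message carries the epoch index."""


class CalibrationError(LosRangeError):
    """No alpha on the finite grid reaches the requested coverage."""


class InsufficientSamplesError(LosRangeError):
    """Too few generated samples to summarize (need at least 2)."""
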