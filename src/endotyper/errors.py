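"""Exception hierarchy shared across the package."""


class EndotyperError(Exception):
    """Base class for all package errors."""


class DomainError(EndotyperError, ValueError):
    """A physiological formula was called outside its domain."""


class DegenerateDataError(EndotyperError, ValueError):
    """Data are degenerate for the requested operation (e.g. zero variance)."""


class DataError(EndotyperError, ValueError):
    """Malformed or inconsistent input data."""


class ConfigError(EndotyperError, ValueError):
    """Invalid configuration."""


class TrainingError(EndotyperError, RuntimeError):
    """Model training diverged or failed."""


class FitError(EndotyperError, RuntimeError):
    """A statistical fit failed despite regularization."""


class LabelingError(EndotyperError, ValueError):
    """Cluster-to-endotype labelling was refused."""


class InsufficientDataError(EndotyperError, ValueError):
    """Too few points for a reliable estimate."""
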