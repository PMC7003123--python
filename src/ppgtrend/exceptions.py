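"""Exception hierarchy for the validation pipeline."""


class PPGTrendError(Exception):
    """Base class for all errors raised by this package."""


class ValidationError(PPGTrendError, ValueError):
    """Malformed or out-of-range input data (files or in-memory series)."""


class ParameterError(PPGTrendError, ValueError):
    """Invalid model or operation parameters."""


class ScheduleError(PPGTrendError, ValueError):
    """Invalid arrhythmia event schedule (overlap, out of range, unordered)."""


class AlignmentError(PPGTrendError, ValueError):
    """Pulse and heart-rate recordings cannot be paired (no overlap)."""


class InsufficientDataError(PPGTrendError, ValueError):
    """Too few samples for the requested statistic."""


class UndefinedCorrelationError(PPGTrendError, ValueError):
    """Residual series has zero variance; the correlation is undefined."""


class RegressionError(PPGTrendError, ValueError):
    """Regression cannot be fitted (too few events or degenerate predictor)."""


class ConfigError(PPGTrendError, ValueError):
    """Invalid run configuration."""
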