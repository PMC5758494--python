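"""Exception hierarchy for the aisrisk pipeline."""


class AisRiskError(Exception):
    """Base class for all package errors."""


class InvalidConfigError(AisRiskError, ValueError):
    """A configuration value violates its invariants."""


class AlignmentError(AisRiskError, ValueError):
    """Inputs that must share a waterbody index do not."""


class ReferentialIntegrityError(AisRiskError, KeyError):
    """A record references an unknown waterbody identifier."""


class EmptyInputError(AisRiskError, ValueError):
    """An operation received an empty collection it cannot handle."""


class InsufficientDataError(AisRiskError, ValueError):
    """Too few points / lags / pairs to estimate the requested quantity."""


class MissingLayerError(AisRiskError, ValueError):
    """A required geometry layer (roads, streams) is absent."""


class ConvergenceError(AisRiskError, RuntimeError):
    """An iterative solver failed to converge within its budget."""

class SingularSystemError(AisRiskError, RuntimeError):
    """A kriging system remained singular after jitter."""


class NoDataError(AisRiskError, ValueError):
    """No data found in the search neighborhood."""


class OutOfExtentError(AisRiskError, ValueError):
    """A point falls outside the prediction grid."""


class UndefinedMetricError(AisRiskError, ValueError):
    """A validation metric is undefined (e.g. single-class labels)."""
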