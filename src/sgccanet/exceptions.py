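"""Exception hierarchy. Everything raised on bad input derives from ValidationError."""


class SgccanetError(Exception):
    """Base class for all package errors."""


class ValidationError(SgccanetError, ValueError):
    """Invalid input data or parameters."""


class ConfigurationError(ValidationError):
    """Inconsistent simulation or pipeline configuration."""


class DegenerateDataError(SgccanetError, ValueError):
    """Input is degenerate for the requested operation (zero variance, empty block, ...)."""


class ImputationError(DegenerateDataError):
    """A missing cell cannot be imputed (e.g. a sample with no observed features)."""


class ConstraintError(ValidationError):
    """An optimisation constraint is infeasible (e.g. l1 bound below 1)."""


class SamplingError(ValidationError):
    """A resampling request cannot be satisfied (undersized group or subsample)."""


class TuningError(SgccanetError):
    """No feasible sparsity value on the grid."""


class ThresholdError(SgccanetError):
    """MI threshold calibration impossible (no usable prior edge)."""
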