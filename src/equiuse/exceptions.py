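"""Exception hierarchy for the equiuse pipeline."""


class EquiuseError(Exception):
    """Base class for all equiuse errors."""


class ConfigError(EquiuseError):
    """Invalid generator or pipeline configuration (e.g. non-increasing cut points)."""


class SchemaError(EquiuseError):
    """A survey file or record collection violates the documented schema."""


class DataError(EquiuseError):
    """Input data violate an operation's preconditions (e.g. negative counts)."""


class FitError(EquiuseError):
    """A model fit failed: separation, empty category, or non-convergence."""


class ScoringError(EquiuseError):
    """Prediction on records a fitted model cannot score (unseen level, missing covariate)."""


class DegenerateDataError(DataError):
    """Data degenerate for the requested operation (e.g. all scores identical)."""
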