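"""Exception and warning hierarchy shared across the package."""


class EffiError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(EffiError):
    """Input table lacks a required column, category or aggregate."""


class DuplicateKeyError(SchemaError):
    """Two rows share the same (department, year, category) key."""


class ConfigError(EffiError):
    """Invalid configuration value (unknown source, bad weight, bad parameter)."""


class DataConsistencyError(EffiError):
    """A subgroup count exceeds its total, or a similar internal contradiction."""


class UnimputableError(EffiError):
    """A department-column series has no observed values to interpolate from."""


class InsufficientDataError(EffiError):
    """Fewer observations than the operation requires."""


class CoverageError(EffiError):
    """Too many departments lack the configured delta year-pair."""


class YearRangeError(EffiError):
    """A requested year lies outside the panel or study window."""


class RankDeficiencyError(EffiError):
    """Singular GLM design matrix; carries the collinear column names."""

    def __init__(self, columns):
        self.columns = list(columns)
        super().__init__(
            "design matrix is rank deficient; collinear columns: "
            + ", ".join(map(str, self.columns))
        )


class UndefinedCorrelationError(EffiError):
    """Zero rank variance in one of the vectors: Spearman rho is undefined."""


class DegenerateScaleWarning(UserWarning):
    """sigma = 0 during standardization; outputs forced to zero."""


class EmptyModelWarning(UserWarning):
    """Backward elimination removed every predictor; intercept-only fit returned."""


class ConstantPredictorWarning(UserWarning):
    """A constant predictor column was dropped before fitting."""


class ExclusionWarning(UserWarning):
    """Departments or cells excluded (unknown department, zero baseline, missing data)."""
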