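"""Exception hierarchy for the slem package."""


class SlemError(Exception):
    """Base class for all package-specific errors."""


class InvalidArgumentError(SlemError, ValueError):
    """An argument violates a documented precondition."""


class DegeneratePredictorError(SlemError, ValueError):
    """A predictor (or response) is constant, so no association is defined."""


class SingularDesignError(SlemError, ValueError):
    """The regression design matrix is rank-deficient."""


class ArchitectureError(SlemError, ValueError):
    """A network layer ended up empty or inconsistent during assembly."""


class SchemaError(SlemError, ValueError):
    """Input columns do not match the labels a model expects."""


class TrainingError(SlemError, ValueError):
    """Training data are degenerate (e.g. a single class)."""


class UndefinedMetricError(SlemError, ValueError):
    """A metric is undefined for the given inputs (e.g. one-class AUROC)."""


class ScreeningError(SlemError, ValueError):
    """Combination screening cannot proceed (e.g. zero patients)."""


class ConfigurationError(SlemError, ValueError):
    """A configuration value or label is unknown."""


class ParseError(SlemError, ValueError):
    """A file could not be parsed; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)
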