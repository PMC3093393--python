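"""Exception hierarchy shared across the package."""


class ContractionBiasError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(ContractionBiasError, ValueError):
    """A parameter value is outside its admissible set."""


class InvalidConfigError(ContractionBiasError, ValueError):
    """A task/run configuration is internally inconsistent."""


class NoRootError(ContractionBiasError, RuntimeError):
    """A bracketed root search failed (no sign change in the bracket)."""


class OutOfRangeError(ContractionBiasError, ValueError):
    """A stimulus length falls outside the declared pixel range."""


class DegenerateFitError(ContractionBiasError, RuntimeError):
    """A fit target carries no usable signal (e.g. all fractions equal)."""


class DegenerateDataError(ContractionBiasError, ValueError):
    """An input variable is constant where variation is required."""


class EmptyBinError(ContractionBiasError, RuntimeError):
    """A requested bin contains no trials."""


class InsufficientTrialsError(ContractionBiasError, ValueError):
    """Too few trials of the required kind for the requested analysis."""


class SubjectMismatchError(ContractionBiasError, ValueError):
    """Paired analysis requested for tables with different subject sets."""


class TooFewReplicatesError(ContractionBiasError, ValueError):
    """Bootstrap replicate count below the supported minimum."""


class SchemaViolationError(ContractionBiasError, ValueError):
    """A trial-table file violates the expected schema."""


class NonIdentifiableCurveError(ContractionBiasError, RuntimeError):
    """The response curve constrains only the noise ratio, not its scale.

    A curve that is flat at 0.5 is produced by every observer with
    sigma1 == sigma2; only the ratio (== 1) is identified.
    """

    def __init__(self, message: str, ratio: float = 1.0):
        super().__init__(message)
        self.ratio = ratio
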