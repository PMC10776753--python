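"""Exception types shared across the pipeline stages."""


class ImgomixError(Exception):
    """Base class for all package errors."""


class InvalidArgumentError(ImgomixError, ValueError):
    """A parameter violates its documented precondition."""


class SingularDesignError(ImgomixError):
    """Rank-deficient design matrix; names the collinear columns."""

    def __init__(self, columns):
        self.columns = list(columns)
        super().__init__(
            f"design matrix is rank deficient; collinear columns: {self.columns}"
        )


class DegenerateResponseError(ImgomixError):
    """Response vector is constant; the model is undefined."""


class UndefinedCorrelationError(ImgomixError):
    """Correlation requested for a zero-variance input."""


class IncompleteMapError(ImgomixError):
    """A parcel map is missing one or more parcels."""


class SchemaMismatchError(ImgomixError):
    """Inputs that must share labels (genes, parcels, subjects) do not."""


class NumericalFailureError(ImgomixError):
    """A numerical routine failed beyond recoverable jitter."""


class EmptyFeatureSetError(ImgomixError):
    """Feature selection produced no features; downstream stages cannot run."""


class FormatError(ImgomixError):
    """A text input file violates its format contract."""


class ConfigError(ImgomixError):
    """Run configuration failed schema validation."""
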