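"""Exception hierarchy shared across the pipeline stages."""


class PrimecropError(Exception):
    """Base class for all package errors."""


class ConfigError(PrimecropError):
    """Invalid configuration (bad thresholds, impossible effect sizes, ...)."""


class InputError(PrimecropError):
    """Malformed or incomplete input data (gaps, missing keys, wrong spans)."""


class QualityError(PrimecropError):
    """Pixel-year fails quality screening (too few composites, long gaps)."""


class DetectionError(PrimecropError):
    """Phenology detection failed (no threshold crossing, non-convergent fit)."""


class CollinearityError(InputError):
    """Panel design matrix is rank deficient."""

    def __init__(self, columns, message=None):
        self.columns = list(columns)
        super().__init__(message or f"collinear design columns: {self.columns}")


class UndefinedAnomalyError(PrimecropError):
    """Standardized anomaly undefined (zero across-year standard deviation)."""


class InsufficientDataError(PrimecropError):
    """A statistical comparison lacks the minimum group sizes."""
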