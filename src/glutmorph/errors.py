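"""Exception hierarchy for the morphometry pipeline."""


class GlutmorphError(Exception):
    """Base class for all package errors."""


class ConfigurationError(GlutmorphError):
    """Invalid cohort design, effect profile, or pipeline configuration."""


class FormatError(GlutmorphError):
    """Input raster is not in the expected format (e.g. not 8-bit RGB)."""


class MeasurementError(GlutmorphError):
    """A morphometric measurement is degenerate (zero calibrated area,
    vascular area exceeding the field, ...)."""


class AggregationError(GlutmorphError):
    """Replicate measurements with incompatible provenance were combined."""


class GeometryError(GlutmorphError):
    """Geometric primitive received a degenerate input (empty point set)."""


class MatchingError(GlutmorphError):
    """Density matching could not satisfy the tolerance above the minimum
    group size.  Carries the best achieved pairwise difference."""

    def __init__(self, message: str, best_difference: float | None = None):
        super().__init__(message)
        self.best_difference = best_difference


class NormalizationError(GlutmorphError):
    """Percent-of-control normalization against a zero control median."""


class RenderError(GlutmorphError):
    """A synthetic field could not be rendered (e.g. lumen placement failed)."""
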