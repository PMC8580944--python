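"""Exception hierarchy for the delineation pipeline."""


class FetalHCError(Exception):
    """Base class for all pipeline errors."""


class EmptyAnnotationError(FetalHCError):
    """The annotated ellipse does not intersect the image canvas."""


class NoDetectionError(FetalHCError):
    """No usable head detection / too few pixels survive thresholding."""


class FitFailureError(FetalHCError):
    """Ellipse fitting failed (degenerate input or non-elliptic conic)."""


class ConfigError(FetalHCError):
    """Invalid or infeasible configuration."""
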