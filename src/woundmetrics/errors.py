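"""Exception hierarchy for the wound-measurement pipeline.

Every pipeline error derives from :class:`WoundMetricsError` so callers
(and the CLI exit-code mapping) can catch the whole family at once.
"""


class WoundMetricsError(Exception):
    """Base class for all pipeline errors."""


class FormatError(WoundMetricsError):
    """Input file is unreadable, truncated, or not in the declared format."""


class ColorMissing(FormatError):
    """A surface file lacks the required per-vertex color attribute."""


class EmptyInput(WoundMetricsError):
    """Input contains no usable geometry or pixels."""


class DegenerateGeometry(WoundMetricsError):
    """Geometry is collinear/coincident where an area-bearing shape is required."""


class EdgeNotClosed(WoundMetricsError):
    """Canny-based segmentation found no closed wound contour."""


class SeedMissing(WoundMetricsError):
    """Seed labels lack a required class (wound or background)."""


class EmptyMask(WoundMetricsError):
    """Segmentation mask has no usable foreground component."""


class ScatterFailed(WoundMetricsError):
    """Vertex scattering could not produce a simple quadrilateral."""


class VihsUnderconstrained(WoundMetricsError):
    """No healthy boundary samples available to anchor the ViHS fit."""


class FieldDegenerate(WoundMetricsError):
    """Spline parameter inversion diverged on too many evaluation cells."""


class EmptyWound(WoundMetricsError):
    """Deviation field contains no in-wound cells to integrate over."""


class StatsInsufficient(WoundMetricsError):
    """Too few groups or values for the repeatability statistics."""


class SpecInvalid(WoundMetricsError):
    """Synthetic wound specification is inconsistent (e.g. wound off-surface)."""


class AnalysisFailed(WoundMetricsError):
    """Too many ViHS instances failed for a trustworthy averaged result."""
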