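"""Exception hierarchy for fgscheck.

Every error raised deliberately by this package derives from
:class:`FgsCheckError`, so callers can distinguish our validation failures
from genuine bugs.
"""


class FgsCheckError(Exception):
    """Base class for all fgscheck errors."""


class FormatError(FgsCheckError):
    """Unreadable or unsupported input file."""


class NoFrameError(FormatError):
    """A video container yielded no frames."""


class ParseError(FgsCheckError):
    """Malformed numeric/tabular input."""


class InsufficientDataError(FgsCheckError):
    """Input has too few samples for the requested computation."""


class ConfigError(FgsCheckError):
    """Malformed layout or protocol configuration."""


class BoundsError(ConfigError):
    """An ROI does not lie fully inside the image it is applied to."""


class LayoutError(ConfigError):
    """Inconsistent phantom layout (missing/overlapping/duplicate regions)."""


class DomainError(FgsCheckError):
    """Argument outside its mathematical domain (e.g. USAF element 0)."""


class ResolutionError(FgsCheckError):
    """A requested synthetic feature cannot be rendered at the pixel grid."""


class GeometryError(FgsCheckError):
    """Geometric construction impossible (band taller than image, annulus
    collision, distorted feature leaving the frame, ...)."""


class SamplingError(FgsCheckError):
    """Sampling grid too coarse for the requested signal."""


class UnresolvedBandError(FgsCheckError):
    """A spectral band has no interior peak or no half-maximum crossing."""


class DetectionError(FgsCheckError):
    """Feature detection failed (too few peaks, non-monotone positions)."""


class PanelError(FgsCheckError):
    """A well panel is missing required wells (e.g. the control)."""


class ComparisonError(FgsCheckError):
    """Reports cannot be compared (incompatible schema versions)."""
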