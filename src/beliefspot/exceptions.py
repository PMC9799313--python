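"""Exception hierarchy.

All package errors derive from :class:`BeliefSpotError` so callers can
catch the package's failures without masking programming errors.
"""


class BeliefSpotError(Exception):
    """Base class for all beliefspot errors."""


class InvalidImageError(BeliefSpotError, ValueError):
    """Input raster violates the image contract (non-finite, negative,
    wrong dimensionality or too small for the Laplacian stencil)."""


class DegenerateDistributionError(BeliefSpotError, ValueError):
    """A statistic is undefined on the given sample (zero variance,
    fewer than two values, or an empty positive support)."""


class NegativeKurtosisError(BeliefSpotError, ArithmeticError):
    """Excess kurtosis of the response is negative, so its fourth root
    is a domain error.  Typically caused by very low SNR; denoise or
    deconvolve the input, or opt into the clamp fallback."""


class DegenerateModelError(BeliefSpotError, ValueError):
    """A reference model cannot be fitted (too few objects, or a
    zero-variance feature)."""


class UnsupportedFormatError(BeliefSpotError, ValueError):
    """File content is not a single-channel 8- or 16-bit grayscale image."""


class PlacementError(BeliefSpotError, RuntimeError):
    """Random source placement failed to satisfy the minimum-separation
    constraint within the attempt budget."""


class ConfigError(BeliefSpotError, ValueError):
    """Run configuration is malformed (unknown keys, bad values)."""
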