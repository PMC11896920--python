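"""Exception hierarchy.

Every error carries a distinct process exit code so the command-line
front end can map failure categories onto shell-visible statuses.
"""


class GutmotionError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class InvalidCenterlineError(GutmotionError):
    """Centerline is degenerate: too few points, zero length, coincident nodes."""

    exit_code = 3


class FormatError(GutmotionError):
    """An input file does not conform to the expected on-disk format."""

    exit_code = 4


class ConfigurationError(GutmotionError):
    """A configuration is internally inconsistent or physically impossible."""

    exit_code = 5


class RegistrationError(GutmotionError):
    """Registration failed (diverged optimisation, non-invertible field...)."""

    exit_code = 6


class ROIError(GutmotionError):
    """Region of interest does not intersect the image field of view."""

    exit_code = 7


class PropagationError(GutmotionError):
    """Centerline propagation is missing a required per-frame deformation."""

    exit_code = 8


class SamplingError(GutmotionError):
    """Requested sample coordinates fall outside the valid image region."""

    exit_code = 9
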