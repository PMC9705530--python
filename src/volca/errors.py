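"""Exception hierarchy shared across the package."""


class VolcaError(Exception):
    """Base class for all package-specific errors."""


class DimensionError(VolcaError):
    """Array shapes or page counts inconsistent with the declared geometry."""


class FormatError(VolcaError):
    """Input file is not in a readable format."""


class ParameterError(VolcaError, ValueError):
    """A parameter violates its physical or logical constraints."""


class DegenerateFrameError(VolcaError):
    """A frame has no usable signal (e.g. zero spatial median)."""


class DegenerateTraceError(VolcaError):
    """A trace cannot be normalized (constant, or non-positive baseline)."""


class DegenerateInputError(VolcaError):
    """Input carries no information for the requested operation."""


class CapacityError(VolcaError):
    """Requested objects cannot be placed in the available volume."""


class FitError(VolcaError):
    """Nonlinear least-squares fit failed to converge."""


class DegenerateFitError(FitError):
    """Input data cannot constrain the fit (e.g. constant profile)."""


class DetectionError(VolcaError):
    """No objects (beads, components) detected where some were required."""


class ConfigurationError(VolcaError):
    """Missing or inconsistent configuration/metadata."""
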