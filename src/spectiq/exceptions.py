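"""Exception hierarchy for spect-iq."""


class SpectIQError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(SpectIQError, ValueError):
    """A physical or algorithmic parameter is out of its valid range."""


class InfeasiblePlanError(SpectIQError, ValueError):
    """A phantom fill plan cannot be realised (e.g. withdrawal >= stock)."""


class GeometryError(SpectIQError, ValueError):
    """Phantom geometry is inconsistent with the requested grid."""


class LayoutError(SpectIQError, RuntimeError):
    """ROI layout search could not satisfy the NEMA placement rules."""


class UndefinedMetricError(SpectIQError, ZeroDivisionError):
    """An image-quality metric is undefined for the given statistics."""


class ConfigurationError(SpectIQError, ValueError):
    """Invalid pipeline / reconstruction configuration."""
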