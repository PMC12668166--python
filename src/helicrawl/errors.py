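"""Exception hierarchy shared across the package."""


class HelicrawlError(Exception):
    """Base class for all package-specific errors."""


class InvalidSpecError(HelicrawlError, ValueError):
    """A robot or phantom specification field violates its invariant."""


class GeometryError(HelicrawlError, ValueError):
    """A requested configuration is geometrically infeasible."""


class CalibrationError(HelicrawlError, ValueError):
    """Calibration inputs are degenerate (rank-deficient, non-invertible)."""


class ConfigurationError(HelicrawlError, ValueError):
    """A run configuration is incomplete or inconsistent."""
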