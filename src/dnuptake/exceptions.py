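"""Package-specific error types."""


class DnUptakeError(Exception):
    """Base class for all package errors."""


class InvalidGeometryError(DnUptakeError, ValueError):
    """Particle geometry is malformed (unknown shape, missing/extra dimensions)."""


class InvalidParameterError(DnUptakeError, ValueError):
    """A model or processing parameter is out of its admissible range."""


class InvalidInputError(DnUptakeError, ValueError):
    """Input arrays are inconsistent (dimension mismatch, window outside image)."""


class InvalidControlError(DnUptakeError, ValueError):
    """Normalization control group is unusable (non-positive mean)."""


class InvalidSpecError(DnUptakeError, ValueError):
    """A synthetic-data specification cannot be realised (e.g. cells do not fit)."""
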