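"""Exception hierarchy for the speckle-sensing pipeline."""


class SpeckleSenseError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(SpeckleSenseError, ValueError):
    """A physical or protocol parameter is non-finite or out of range."""


class DegenerateGeometryError(SpeckleSenseError, ValueError):
    """An optical-geometry formula was evaluated at a singular configuration
    (zero field, zero path length, or a field perpendicular to the beam)."""


class DegenerateInputError(SpeckleSenseError, ValueError):
    """The input carries no usable signal (constant frame, zero-energy series)."""


class InvalidInputError(SpeckleSenseError, ValueError):
    """Structurally invalid input (shape mismatch, too few frames, ...)."""


class NyquistError(InvalidParameterError):
    """The requested analysis frequency is at or above half the sampling rate."""


class ConfigError(SpeckleSenseError, ValueError):
    """A run-configuration file failed validation; the message names the field."""
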