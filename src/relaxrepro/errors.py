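"""Exception types shared across the package."""

__all__ = [
    "RelaxReproError",
    "ConfigError",
    "UnsupportedProtocolError",
    "ContrastStateError",
    "DegenerateROIError",
    "EmptyMeasurementError",
    "UndefinedAgreementError",
]


class RelaxReproError(Exception):
    """Base class for package errors."""


# Deliberately not a ValueError: pydantic would wrap it into a
# ValidationError inside model validators, hiding the package error type.
class ConfigError(RelaxReproError):
    """Invalid configuration value (non-positive dimension, negative SD, ...)."""


class UnsupportedProtocolError(RelaxReproError, ValueError):
    """Requested (field strength, weighting) has no preset."""


class ContrastStateError(RelaxReproError, ValueError):
    """Contrast applied to a phantom that is already post-contrast."""


class DegenerateROIError(RelaxReproError, ValueError):
    """An ROI is empty or was perturbed into degeneracy."""


class EmptyMeasurementError(RelaxReproError, ValueError):
    """A measurement retained zero voxels (mask or fit excluded everything)."""


class UndefinedAgreementError(RelaxReproError, ValueError):
    """Agreement statistic undefined (e.g. both vectors constant)."""
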