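"""Exception hierarchy used across the package."""


class HallmarkSurvError(Exception):
    """Base class for all package errors."""


class FormatError(HallmarkSurvError):
    """A file does not conform to the expected on-disk format."""


class ValidationError(HallmarkSurvError):
    """Parsed content violates a container invariant."""


class ConfigurationError(HallmarkSurvError):
    """A configuration value is out of range or inconsistent."""


class EstimationError(HallmarkSurvError):
    """A statistical estimate cannot be computed from the given data."""


class InsufficientDataError(EstimationError):
    """Too few observations (or events) for the requested analysis."""
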