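"""Exception hierarchy used across the package."""


class CSFMobilityError(Exception):
    """Base class for all package errors."""


class GeometryError(CSFMobilityError):
    """A phantom structure does not fit the simulation grid."""


class ConfigurationError(CSFMobilityError):
    """An invalid or inconsistent configuration value."""


class SignalQualityError(CSFMobilityError):
    """A physiological trace is unusable (e.g. too few detectable peaks)."""


class FormatError(CSFMobilityError):
    """A file could not be parsed in the expected format."""


class DependencyError(CSFMobilityError):
    """A pipeline stage was invoked before its upstream stage produced output."""
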