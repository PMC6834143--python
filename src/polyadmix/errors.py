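"""Exception types used across the package."""


class PolyadmixError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(PolyadmixError, ValueError):
    """A parameter is outside its valid domain."""


class ConfigurationError(PolyadmixError, ValueError):
    """A scenario or therapy configuration is inconsistent or infeasible."""


class CalibrationError(PolyadmixError, RuntimeError):
    """Mapping calibration cannot be performed with the given inputs."""


class StructuralError(PolyadmixError, ValueError):
    """Shapes or lineages of objects do not match (e.g. genotype vs architecture)."""


class FingerprintMismatchError(StructuralError):
    """A saved mapping does not belong to the supplied genetic architecture."""
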