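"""Exception types shared across the package."""


class SamDenoiseError(Exception):
    """Base class for package errors."""


class ParameterError(SamDenoiseError, ValueError):
    """An argument violates a documented precondition."""


class FormatError(SamDenoiseError, ValueError):
    """An on-disk file does not match the expected layout or its sidecar."""


class CoverageError(SamDenoiseError, RuntimeError):
    """Aggregation left at least one voxel with zero total weight."""


class RegistrationError(SamDenoiseError, RuntimeError):
    """Rigid registration cannot be estimated (e.g. constant images)."""
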