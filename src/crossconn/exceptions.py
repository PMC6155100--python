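"""Exception types shared across the package."""


class CrossConnError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(CrossConnError, ValueError):
    """A user-supplied parameter is invalid (out of range, inconsistent, ...)."""


class ConstructionError(CrossConnError, RuntimeError):
    """A synthetic object could not be assembled (e.g. degenerate covariance)."""


class SchemaError(CrossConnError, ValueError):
    """A file does not match the expected on-disk schema."""
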