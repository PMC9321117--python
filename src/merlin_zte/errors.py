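"""Exception hierarchy shared across the package."""


class MerlinError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(MerlinError, ValueError):
    """Invalid parameter combination or malformed configuration."""


class GeometryError(MerlinError, ValueError):
    """Degenerate or out-of-range geometric input."""


class DegenerateInputError(MerlinError, ValueError):
    """Input that is empty, flat or otherwise carries no usable signal."""


class ContainerError(MerlinError, IOError):
    """Malformed or incompatible acquisition container."""
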