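"""Exception types shared across the package."""


class NasodoseError(Exception):
    """Base class for package errors."""


class ConfigurationError(NasodoseError, ValueError):
    """Invalid run or geometry configuration."""


class DomainError(NasodoseError, ValueError):
    """Input outside the mathematical or physical domain of an operation."""


class PlacementError(NasodoseError, ValueError):
    """Spray origin or axis anchored at an invalid location."""


class IntegrationError(NasodoseError, RuntimeError):
    """Droplet integration produced a non-finite state."""


class InterpolationError(NasodoseError, ValueError):
    """A curve does not cover the requested interpolation interval."""
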