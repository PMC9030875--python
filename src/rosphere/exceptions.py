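"""Exception hierarchy shared across the package."""


class RosphereError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(RosphereError):
    """A tabular input is missing a required column or has an unusable header."""


class ValidationError(RosphereError, ValueError):
    """A value violates a documented invariant (non-positive radius, bad enum, ...)."""


class NoSphereOfInfluenceError(ValidationError):
    """The intracellular/extracellular concentration contrast has the wrong sign
    for the requested direction, so no threshold radius exists."""


class GridTooShortError(RosphereError):
    """A time grid ends before the concentration profile crosses the seawater
    background, so no grid-based threshold can be reported."""


class LayoutTooLargeError(ValidationError):
    """A requested layout would exceed the configured point-count cap."""
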