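"""Exception hierarchy for canopydx.

All domain-validation failures derive from :class:`ValueError` so callers
can catch them generically; I/O failures derive from :class:`IOError`.
"""


class InputDomainError(ValueError):
    """An argument lies outside its documented domain (e.g. channel > 255)."""


class ImageReadError(IOError):
    """The image file could not be read or decoded."""


class UnsupportedImageError(ValueError):
    """The image is readable but not an 8-bit-per-channel raster."""


class UnderdeterminedFitError(ValueError):
    """Too few distinct cover values to fit a quadratic."""


class DegenerateModelError(ValueError):
    """The quadratic coefficient a is zero where a parabola is required."""


class UnknownCultivarError(KeyError):
    """The cultivar name does not resolve in the registry."""


class DegenerateInputError(ValueError):
    """Paired observations are too small or have zero variance."""
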