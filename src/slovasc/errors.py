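"""Exception hierarchy shared across the package."""


class SlovascError(Exception):
    """Base class for all package-specific failures."""


class DecodeError(SlovascError):
    """An input file could not be decoded as the expected format."""


class ShapeError(SlovascError):
    """An array does not have the required shape or dimensionality."""


class EncodingError(SlovascError):
    """A label image contains values outside the declared encoding."""


class ConfigError(SlovascError):
    """A configuration file could not be parsed."""


class ParameterError(SlovascError):
    """A parameter value is outside its valid range."""


class CapabilityError(SlovascError):
    """A requested analysis cannot be carried out with the available inputs
    (e.g. peripapillary zones without a detected optic disc)."""
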