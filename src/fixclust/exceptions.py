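"""Exception hierarchy shared across the package."""


class FixclustError(Exception):
    """Base class for all package-specific errors."""


class InputError(FixclustError):
    """A file could not be read or an input value is unusable."""


class FormatError(FixclustError):
    """An input file was readable but malformed (non-rectangular, NaNs...)."""


class ParameterError(FixclustError, ValueError):
    """A parameter violates its documented constraints."""


class FitError(FixclustError):
    """A model fit failed (no contact region, negative modulus, ...)."""


class ConfigError(FixclustError):
    """A pipeline configuration is invalid; message names the key path."""
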