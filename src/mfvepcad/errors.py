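"""Exception hierarchy for the mfVEP CAD pipeline."""


class MfvepError(Exception):
    """Base class for all package errors."""


class FormatError(MfvepError):
    """A file or in-memory object violates the documented record layout."""


class DegenerateInputError(MfvepError):
    """Numerically degenerate input (flat trace, zero noise denominator, ...)."""


class ConfigError(MfvepError):
    """Invalid pipeline configuration."""
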