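"""Exception hierarchy for the gazevote pipeline."""


class GazevoteError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(GazevoteError):
    """A tabular input is missing required columns or carries unknown ones."""


class ParseError(GazevoteError):
    """A cell could not be converted to its declared type."""


class DataValidationError(GazevoteError):
    """A record violates a structural invariant (e.g. zero-duration fixation)."""


class IntegrityError(GazevoteError):
    """Cross-record consistency failure (e.g. a race without exactly one winner)."""


class DegenerateInputError(GazevoteError):
    """A statistical operation received input on which it is undefined."""


class ConfigError(GazevoteError):
    """Invalid simulation or pipeline configuration."""
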