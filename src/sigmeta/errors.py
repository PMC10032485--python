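"""Exception hierarchy.

``SigmetaError`` is the base class for every error the library raises on
bad data or bad configuration, so callers (and the CLI) can distinguish
pipeline problems from programming errors.
"""


class SigmetaError(Exception):
    """Base class for all sigmeta errors."""


class TaxonomyError(SigmetaError):
    """Structural problem in a taxonomy table (cycle, duplicate, missing node)."""


class DataError(SigmetaError):
    """Malformed or degenerate input data."""


class ConfigError(SigmetaError):
    """Invalid parameter or file-format configuration."""
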