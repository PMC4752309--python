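"""Exception hierarchy.

Exit-code mapping used by the CLI: ConfigError -> 2, DataError -> 3.
"""


class SpongeMirError(Exception):
    """Base class for all package errors."""


class ConfigError(SpongeMirError):
    """Invalid configuration (bad thresholds, non-positive lengths, ...)."""


class DataError(SpongeMirError):
    """Malformed or inconsistent input data."""


class PlacementError(SpongeMirError):
    """Hairpins could not be placed on the genome without overlap."""


class ReportError(SpongeMirError):
    """A report was requested from incomplete pipeline artifacts."""
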