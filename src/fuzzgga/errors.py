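"""Exception hierarchy for fuzzy-partitioning errors."""


class FuzzGGAError(Exception):
    """Base class for all package errors."""


class ValidationError(FuzzGGAError):
    """An input violates a documented precondition."""


class ConfigError(FuzzGGAError):
    """An invalid run configuration value."""


class ParseError(FuzzGGAError):
    """A delimited-text file could not be parsed as a numeric table."""


class DegeneratePartitionError(FuzzGGAError):
    """A partition collapsed: fewer than two clusters, or coincident centroids."""
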