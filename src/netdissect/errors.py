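"""Exception hierarchy shared across the package."""


class NetdissectError(Exception):
    """Base class for all package errors."""


class ConfigError(NetdissectError):
    """Invalid generator or pipeline configuration."""


class ValidationError(NetdissectError):
    """Malformed input data (graphs, tables, sequences, motifs)."""


class UndefinedFitError(NetdissectError):
    """A fit was requested on data that cannot support it."""
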