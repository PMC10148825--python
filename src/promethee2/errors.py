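"""Exception hierarchy shared across the package."""


class Promethee2Error(Exception):
    """Base class for all package errors."""


class ElicitationError(Promethee2Error, ValueError):
    """Invalid linguistic input: unknown label, empty panel, ragged panel."""


class ConfigurationError(Promethee2Error, ValueError):
    """Invalid criteria, weights, preference-function or run configuration."""


class DomainError(Promethee2Error, ValueError):
    """Input outside the mathematical domain of an operation."""


class ParseError(Promethee2Error, ValueError):
    """Malformed input file; message names the offending line/column/cell."""
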