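"""Exception hierarchy shared across the package."""


class LaphaseError(Exception):
    """Base class for all package errors."""


class ConfigError(LaphaseError, ValueError):
    """Invalid configuration (degenerate SDs, out-of-range fractions, ...)."""


class DomainError(LaphaseError, ValueError):
    """Numerically invalid input to a formula (nonpositive area, BSA, ...)."""


class OrderingError(LaphaseError, ValueError):
    """A phasic volume triple violates lav_min <= lav_ac <= lav_max."""


class SchemaError(LaphaseError, ValueError):
    """A CSV table fails schema validation."""
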