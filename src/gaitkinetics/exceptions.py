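"""Exception types shared across the package."""


class GaitKineticsError(Exception):
    """Base class for package errors."""


class ConfigError(GaitKineticsError, ValueError):
    """Invalid configuration (counts, rates, rosters, unknown variants)."""


class DimensionError(GaitKineticsError, ValueError):
    """Array shape or width mismatch."""


class InvalidInputError(GaitKineticsError, ValueError):
    """Input violates an operation precondition (too short, NaN, ...)."""


class DegenerateInputError(GaitKineticsError, ValueError):
    """Metric input is degenerate (constant series, zero range)."""


class SchemaError(GaitKineticsError, ValueError):
    """On-disk dataset does not follow the documented schema."""
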