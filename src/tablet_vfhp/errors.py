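"""Exception hierarchy shared across the package."""


class TabletError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(TabletError, ValueError):
    """An input violates a documented precondition (range, dtype, shape)."""


class DimensionMismatchError(ValidationError):
    """Frames/masks that must share dimensions do not."""


class RealTimeConstraintError(TabletError):
    """Per-frame processing budget exceeds the camera frame period."""


class DegenerateDataError(TabletError, ValueError):
    """Data admit no test decision (all-zero differences, zero variance)."""


class UnbalancedDesignError(TabletError, ValueError):
    """Cohort table is not a complete balanced participant x condition x trial grid."""


class NoContactError(TabletError, ValueError):
    """Operation requires at least one stylus contact sample."""


class SchemaError(TabletError, ValueError):
    """A CSV/YAML file does not match the documented schema."""


class ConfigError(SchemaError):
    """Run configuration contains unknown keys or out-of-range values."""
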