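"""Exception hierarchy for the rollgait pipeline.

Every stage raises a subclass of :class:`RollgaitError`, so callers (and the
CLI) can catch pipeline failures without masking programming errors.
"""


class RollgaitError(Exception):
    """Base class for all rollgait pipeline errors."""


class ConfigError(RollgaitError, ValueError):
    """Invalid simulation or pipeline configuration."""


class SegmentationError(RollgaitError):
    """Step detection failed (e.g. too few vertical-acceleration peaks)."""


class WindowDegeneracyError(RollgaitError):
    """A step window is too short to carve out the gait-phase sub-windows."""


class InsufficientStepsError(RollgaitError):
    """Fewer than two steps on one side; trial-level aggregation undefined."""


class MissingKinematicsError(RollgaitError):
    """Gold-standard kinematics (COM trajectory / BOS boundary) unavailable."""


class DegenerateStatisticError(RollgaitError):
    """A statistic is undefined on this input (zero-variance differences etc.)."""


class SchemaError(RollgaitError, ValueError):
    """A file read back from disk does not match the documented schema."""
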