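"""Exception hierarchy.

All errors raised by this package derive from :class:`ImuGaitError` so callers
can catch the package's failures without masking programming errors.
"""


class ImuGaitError(Exception):
    """Base class for all imugait errors."""


class FormatError(ImuGaitError, ValueError):
    """A file did not match the documented CSV/HDF5 dialect."""


class SyncError(ImuGaitError, ValueError):
    """Timestamps are non-monotone, non-uniform, or disagree across sensors."""


class EmptyInputError(ImuGaitError, ValueError):
    """Fewer samples than the operation can work with."""


class TopologyError(ImuGaitError, ValueError):
    """Sensor placements are missing or duplicated."""


class ArgumentError(ImuGaitError, ValueError):
    """An argument violates a documented precondition."""


class DegenerateAxesError(ImuGaitError, ValueError):
    """Axis pair too close to parallel (or zero) to span a frame."""


class SingularityError(ImuGaitError, ValueError):
    """Cardan decomposition requested within ~1e-6 deg of gimbal lock."""


class SegmentationError(ImuGaitError, ValueError):
    """Too few gait events found to segment the series into cycles."""


class InitializationError(ImuGaitError, RuntimeError):
    """Optimization could not start (non-finite residual at the initial guess)."""


class ConfigError(ImuGaitError, ValueError):
    """Run configuration failed schema validation."""
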