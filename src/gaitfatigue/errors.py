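"""Exception types shared across the pipeline."""


class GaitFatigueError(Exception):
    """Base class for all package-specific errors."""


class ImuFormatError(GaitFatigueError, ValueError):
    """Malformed IMU stream: missing columns, empty file, unparsable rows."""


class SampleRateError(GaitFatigueError, ValueError):
    """Timestamp spacing inconsistent with the declared sampling rate."""


class ConfigError(GaitFatigueError, ValueError):
    """Invalid simulator or pipeline configuration."""


class BoundsError(GaitFatigueError, ValueError):
    """A window or cycle lies outside the extent of its recording."""


class AggregationError(GaitFatigueError, ValueError):
    """A window produced no complete gait cycles, so no aggregate exists."""


class PipelineError(GaitFatigueError, RuntimeError):
    """Unrecoverable cohort-level failure (e.g. too few usable subjects)."""
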