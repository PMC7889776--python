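"""Exception hierarchy.

Everything raised on a *scientific* precondition violation (bad map values,
degenerate fits, empty ROIs) derives from :class:`SuvleanError` so callers can
distinguish domain failures from programming errors.
"""


class SuvleanError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(SuvleanError):
    """A generator or study configuration is infeasible (e.g. requested
    compartment volumes do not fit on the voxel grid, or truncation bounds
    exclude the target mean)."""


class SegmentationError(SuvleanError):
    """An attenuation map contains a voxel value that cannot be assigned to
    any tissue label within tolerance."""


class FitError(SuvleanError):
    """A regression is degenerate (rank-deficient design, constant regressor,
    all-zero volumes)."""


class EmptyROIError(SuvleanError):
    """A region of interest contains no voxels."""


class PipelineError(SuvleanError):
    """A study stage failed; the message names the stage."""

    def __init__(self, stage: str, message: str = ""):
        self.stage = stage
        super().__init__(f"stage '{stage}' failed" + (f": {message}" if message else ""))
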