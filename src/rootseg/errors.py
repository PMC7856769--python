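"""Exception hierarchy for rootseg."""


class RootsegError(Exception):
    """Base class for all rootseg errors."""


class VolumeIOError(RootsegError):
    """Unreadable, ambiguous or metadata-less volume files."""


class PhantomGeometryError(RootsegError):
    """Phantom geometry does not fit the grid or is unrealizable."""


class SegmentationError(RootsegError):
    """Invalid markers/corrections or degenerate segmentation input."""


class FrameFitError(RootsegError):
    """Degenerate landmark configuration for the tooth coordinate frame."""


class RootSeparationError(RootsegError):
    """Root partition below the cutting plane did not yield three roots."""


class RegistrationError(RootsegError):
    """Empty reference mask or non-converged rigid registration."""


class StatsError(RootsegError):
    """Degenerate input to an agreement/test statistic."""
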