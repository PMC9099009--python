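"""Exception hierarchy shared by all pipeline stages."""


class TortuflowError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(TortuflowError):
    """Unreadable or structurally invalid input file."""


class ConfigError(TortuflowError):
    """Out-of-range or inconsistent configuration value."""


class PhantomSpecError(TortuflowError):
    """Invalid synthetic-phantom specification (degenerate geometry etc.)."""


class DegenerateInputError(TortuflowError):
    """Input is formally valid but carries no usable signal (e.g. zero contrast)."""


class SegmentationError(TortuflowError):
    """No acceptable artery segmentation found in the configured j range."""


class UnreachableError(TortuflowError):
    """Target voxel not reached by the fast-marching front."""


class ConvergenceError(TortuflowError):
    """Gradient-descent backtrace stagnated before reaching the source."""


class ComplicatedGeometryError(TortuflowError):
    """Vessel geometry unsupported by single-path tracking (e.g. loop-back)."""


class NoVesselSignalError(TortuflowError):
    """Magnitude threshold left no pixels in the flow ROI."""
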