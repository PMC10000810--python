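"""Exception hierarchy shared by all helict modules."""


class HelictError(Exception):
    """Base class for all helict errors."""


class GeometryError(HelictError, ValueError):
    """Inconsistent or invalid acquisition geometry."""


class ModeError(GeometryError):
    """Operation requested for the wrong scan mode (helical vs standard)."""


class ResolutionError(HelictError, ValueError):
    """Requested structure cannot be represented at the given voxel size."""


class DataError(HelictError, ValueError):
    """Input data violate an operation's preconditions (e.g. nonpositive
    intensities beyond the mask budget)."""


class FormatError(HelictError, ValueError):
    """File cannot be read or written in the expected format."""


class MetricError(HelictError, ValueError):
    """A quality metric is undefined for the given input (e.g. zero
    background standard deviation)."""
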