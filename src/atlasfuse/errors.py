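"""Exception hierarchy shared across atlasfuse."""


class AtlasFuseError(Exception):
    """Base class for all atlasfuse errors."""


class FormatError(AtlasFuseError):
    """A file could not be read or has unsupported content (non-3D, oblique axes, ...)."""


class GridMismatchError(AtlasFuseError):
    """Two grid-based objects do not share the same geometry."""


class DegenerateMaskError(AtlasFuseError):
    """A mask is empty or covers the whole grid where a proper mask is required."""


class DegenerateROIError(AtlasFuseError):
    """An image has zero intensity variance inside the region of interest."""


class ParameterError(AtlasFuseError):
    """An invalid parameter value (negative margin, bad weight vector, ...)."""
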