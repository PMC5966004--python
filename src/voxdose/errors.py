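"""Exception hierarchy."""


class VoxDoseError(Exception):
    """Base class for all package errors."""


class ParameterError(VoxDoseError, ValueError):
    """An invalid or missing numeric parameter."""


class ValidationError(VoxDoseError, ValueError):
    """A data container violates one of its invariants."""


class GeometryError(VoxDoseError, ValueError):
    """Incompatible voxel sizes or array shapes."""


class KernelFormatError(VoxDoseError, ValueError):
    """A kernel file is malformed; the message names the offending field."""


class PackingError(VoxDoseError, RuntimeError):
    """Lesion placement failed; try a larger grid or fewer lesions."""


class MissingLesionError(VoxDoseError, KeyError):
    """A requested lesion label is absent from the mask."""
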