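"""Exception hierarchy for maxalign."""


class MaxalignError(Exception):
    """Base class for all maxalign errors."""


class MeshIOError(MaxalignError):
    """File could not be read or written."""


class MeshFormatError(MaxalignError):
    """File content does not parse as the expected format.

    Messages name the byte offset (binary STL) or line number (ASCII STL)
    of the first offending record.
    """


class MeshValidationError(MaxalignError):
    """Mesh violates a structural invariant (indices, normals, finiteness)."""


class ROIError(MaxalignError):
    """Region-of-interest definition is empty, out of range, or stale."""


class DegenerateGeometryError(MaxalignError):
    """Geometric input has insufficient rank (collinear points, zero-area triangle)."""


class RegistrationError(MaxalignError):
    """ICP failed (no usable correspondences, non-finite residual)."""


class DeviationError(MaxalignError):
    """Deviation analysis could not be performed as requested."""


class PipelineError(MaxalignError):
    """A pipeline stage failed; message names the stage."""
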