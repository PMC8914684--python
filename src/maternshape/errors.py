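"""Exception hierarchy shared across the package."""


class MaternShapeError(Exception):
    """Base class for all package errors."""


class InvalidArgumentError(MaternShapeError, ValueError):
    """An argument violates a documented precondition."""


class ObjParseError(MaternShapeError, ValueError):
    """Malformed Wavefront OBJ input.

    Carries the 1-based line number of the offending record.
    """

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


class TopologyError(MaternShapeError, ValueError):
    """Meshes do not share vertex count / face list where required."""


class EmptySectionError(MaternShapeError, ValueError):
    """A slicing plane does not intersect the mesh."""


class RegionNotFoundError(MaternShapeError, LookupError):
    """No cross-section loop matches the requested body region."""


class LandmarkError(MaternShapeError, LookupError):
    """An anatomical landmark search failed; message names the band."""


class SingularDesignError(MaternShapeError, ValueError):
    """Regression design matrix is rank deficient."""


class GenerationError(MaternShapeError, RuntimeError):
    """Procedural avatar generation could not meet its tolerance."""
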