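"""Exception hierarchy for lincsopt."""


class LincsoptError(Exception):
    """Base class for all lincsopt errors."""


class ParseError(LincsoptError):
    """A topology or coordinate document could not be parsed."""

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


class ValidationError(LincsoptError):
    """A structural invariant of a topology or configuration is violated."""


class DegenerateGeometryError(LincsoptError):
    """Geometry is degenerate for the requested operation.

    Raised for coincident constrained sites, collinear virtual-site
    parents, or a scaffold with no well-conditioned parent frame.
    """


class NonConvergentError(LincsoptError):
    """The truncated-series expansion cannot converge (spectral radius >= 1)."""


class MassFloorError(LincsoptError):
    """An equimomental transform drove a point mass below the mass floor.

    The position of a (near-)massless point is undefined in the
    homogeneous-coordinate parameterization, so such proposals must be
    rejected by the caller.
    """
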