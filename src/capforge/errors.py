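"""Exception hierarchy for capforge.

All capforge errors derive from :class:`CapforgeError` so callers (and the CLI)
can distinguish usage/validation problems from genuine runtime failures.
"""


class CapforgeError(Exception):
    """Base class for all capforge errors."""


class ValidationError(CapforgeError, ValueError):
    """Invalid argument or input object (bad parameter, degenerate geometry)."""


class ParseError(CapforgeError):
    """A file could not be parsed in its declared format."""


class TopologyError(CapforgeError):
    """Mesh topology violates a precondition (non-manifold, open, ...)."""


class NoIntersectionError(CapforgeError):
    """A cutting plane does not intersect the surface."""


class SnapError(CapforgeError):
    """A point is too far from a curve/surface to be snapped onto it.

    Carries ``distance``, the offending gap in mesh units.
    """

    def __init__(self, message: str, distance: float | None = None):
        super().__init__(message)
        self.distance = distance


class ConvergenceError(CapforgeError):
    """An iterative procedure failed to converge; carries the last delta."""

    def __init__(self, message: str, last_delta: float | None = None):
        super().__init__(message)
        self.last_delta = last_delta


class RecipeError(CapforgeError):
    """A montage curve recipe references an anchor that is not yet placed."""


class RepairError(CapforgeError):
    """Mesh repair could not reach a defect-free state.

    Carries ``report``, the residual defect census.
    """

    def __init__(self, message: str, report=None):
        super().__init__(message)
        self.report = report


class ResourceError(CapforgeError):
    """A requested problem size exceeds a documented guard."""
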