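"""Exception hierarchy.

All package errors derive from :class:`HelixGeomError` so callers can catch
everything with one clause; ``ValidationError`` doubles as ``ValueError`` for
ergonomic use in scripts.
"""


class HelixGeomError(Exception):
    """Base class for all helixgeom errors."""


class ValidationError(HelixGeomError, ValueError):
    """A spec, trace or parameter violates an invariant; message names the field."""


class GeometryError(HelixGeomError):
    """Degenerate or ill-conditioned geometry (coincident points, rank-deficient fit)."""


class StructureError(HelixGeomError):
    """A structure file could not be parsed or a helix selection could not be resolved."""
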