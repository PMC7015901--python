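"""Exception and warning types shared across the package."""


class SeedmorphError(Exception):
    """Base class for all package errors."""


class InvalidPolygonError(SeedmorphError, ValueError):
    """Cell outline is not a valid simple polygon."""


class InvalidArgumentError(SeedmorphError, ValueError):
    """An argument violates a documented precondition."""


class AmbiguousTopologyError(SeedmorphError):
    """Layer cells do not form a single unambiguous chain."""


class InvalidSpecError(SeedmorphError, ValueError):
    """A synthetic-tissue specification is infeasible or inconsistent."""


class SchemaError(SeedmorphError, ValueError):
    """An on-disk table or feature collection is missing required fields."""


class UnsupportedGeometryError(SchemaError):
    """A geometry type other than a simple Polygon was supplied."""


class OutOfBoundsError(SeedmorphError, ValueError):
    """A cell falls outside the requested raster canvas."""


class DegenerateShapeWarning(UserWarning):
    """The rectangle model is degenerate for this cell (P <= 2L)."""


class OverlapWarning(UserWarning):
    """Two cells overlap in a rendered label image; later cell wins."""


class SplitLabelWarning(UserWarning):
    """A label in a mask had multiple connected components and was split."""
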