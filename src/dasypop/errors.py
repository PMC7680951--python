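"""Exception hierarchy shared across the pipeline."""


class DasypopError(Exception):
    """Base class for all package errors."""


class SchemaError(DasypopError):
    """A required attribute or field is missing from an input."""


class GeometryError(DasypopError):
    """An input geometry has the wrong type or is invalid."""


class ValidationError(DasypopError):
    """An input violates a stated invariant (e.g. negative population)."""


class AlignmentError(DasypopError):
    """Two rasters do not share the same grid."""


class EmptyZoneError(DasypopError):
    """Rasterization or zonal statistics produced no cells for the input."""


class NoNeighborError(DasypopError):
    """A census unit shares no positive-length border with any other unit."""


class AggregationStallError(DasypopError):
    """The dissolve procedure cannot reach its target unit count."""


class UndefinedDistanceError(DasypopError):
    """A distance-to-edge surface is undefined (uniform mask, no edge)."""
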