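"""Exception hierarchy for facet-morphometry operations."""


class FacetMorphError(Exception):
    """Base class for all package errors."""


class FormatError(FacetMorphError):
    """Unreadable file or unsupported mesh format."""


class DegenerateInputError(FacetMorphError):
    """Input geometry cannot support the requested operation."""


class CoplanarPointsError(DegenerateInputError):
    """All points lie on a plane; a sphere is unidentifiable."""


class CollinearPointsError(DegenerateInputError):
    """Points lie on a line; a circle/plane is unidentifiable."""


class NoIntersectionError(FacetMorphError):
    """A cutting plane misses the mesh entirely."""


class DegenerateSectionError(FacetMorphError):
    """A plane grazes the mesh yielding only isolated points."""


class UndefinedAngleError(FacetMorphError):
    """An angle between vectors is undefined (zero vector, possibly after projection)."""


class AmbiguousFrameError(FacetMorphError):
    """Vertex PCA cannot orient the patch; a landmark file is needed."""


class ValidationError(FacetMorphError):
    """A user-supplied specification or file fails its invariants."""


class InfeasibleSpecError(ValidationError):
    """A synthetic-surface specification cannot be realized."""


class DegeneratePartitionError(FacetMorphError):
    """Two-sphere partition collapsed; the surface is effectively unicondylar."""


class InsufficientRegionError(FacetMorphError):
    """A vertex subset is too small for the requested regional fit."""


class SchemaError(FacetMorphError):
    """A report/measurement file does not match the expected schema."""
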