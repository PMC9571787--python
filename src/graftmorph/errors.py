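"""Exception hierarchy for graftmorph."""


class GraftMorphError(Exception):
    """Base class for all graftmorph errors."""


class MetadataError(GraftMorphError):
    """Image header metadata is missing or inconsistent (e.g. no voxel spacing)."""


class MeshError(GraftMorphError):
    """A mesh violates a structural requirement (empty, non-manifold, ...)."""


class NonWatertightError(MeshError):
    """A mesh required to enclose a volume has open boundary edges."""

    def __init__(self, message: str, boundary_edges: int = -1):
        super().__init__(message)
        self.boundary_edges = boundary_edges


class EmptySegmentationError(GraftMorphError):
    """Thresholding produced an empty mask."""


class UndefinedStatisticError(GraftMorphError):
    """A statistic is undefined for the given input (e.g. all grades tied)."""


class ConfigError(GraftMorphError):
    """Pipeline configuration is invalid or references missing files."""
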