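"""Exception hierarchy for glycomesh.

All package errors derive from :class:`GlycomeshError` so callers can catch
one base class; parameter/validation problems additionally derive from
``ValueError``.
"""


class GlycomeshError(Exception):
    """Base class for all glycomesh errors."""


class ParameterError(GlycomeshError, ValueError):
    """Invalid or infeasible parameter combination."""


class DegenerateExtentError(ParameterError):
    """Extent too small to hold a meaningful point pattern."""


class ResolutionError(ParameterError):
    """Voxel/pixel size too coarse for the requested measurement."""


class InsufficientDataError(GlycomeshError):
    """Too few points/samples to compute the requested statistic."""


class EmptyResultError(InsufficientDataError):
    """An estimator was left with zero usable samples."""


class TriangulationError(GlycomeshError):
    """Delaunay triangulation failed (degenerate, e.g. collinear, input)."""


class TopologyError(GlycomeshError):
    """Network rendering contains no enclosed openings."""


class GroupingError(GlycomeshError):
    """Per-tip grouping requested on a pattern without tip identities."""


class CoatingModelError(GlycomeshError):
    """Coating correction produced non-physical (<= 0) core diameters for
    more than the tolerated fraction of cross-sections."""


class PointTableError(GlycomeshError):
    """Point-table file could not be parsed into a pattern."""


class StageError(GlycomeshError):
    """Pipeline stage failure; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
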