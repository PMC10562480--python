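"""Exception hierarchy.

All package errors derive from :class:`HabitatGraphError` so pipeline code can
distinguish expected per-subject data problems (degenerate ROIs, tiny habitats)
from programming errors.
"""


class HabitatGraphError(Exception):
    """Base class for all habitatgraph errors."""


class ParameterError(HabitatGraphError, ValueError):
    """An input parameter violates a documented invariant."""


class DegenerateROIError(HabitatGraphError):
    """ROI intensities have zero range; the low/high habitat split is undefined."""


class UnimodalROIError(HabitatGraphError):
    """The two GMM components collapsed onto each other; no bimodal structure."""


class InsufficientPointsError(HabitatGraphError):
    """Too few points for the requested graph construction."""


class DegenerateGeometryError(HabitatGraphError):
    """Point set admits no triangulation (fewer than 3 points or all collinear)."""


class UndefinedFeatureError(HabitatGraphError):
    """A feature is undefined for this input (e.g. max/min ratio with min = 0)."""


class EmptyMatrixError(HabitatGraphError):
    """Graph run-length matrix contains no runs."""


class StratificationError(HabitatGraphError):
    """A class has too few members for the requested stratified CV split."""


class DegenerateLabelsError(HabitatGraphError):
    """Label dichotomization is impossible (e.g. constant scores under median rule)."""


class UndefinedROCError(HabitatGraphError):
    """ROC analysis requires both classes to be present."""
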