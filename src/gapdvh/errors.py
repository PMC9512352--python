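"""Named exception classes raised across the package."""


class GapDvhError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(GapDvhError, ValueError):
    """A radiobiological or statistical parameter is out of its domain."""


class ConsistencyError(GapDvhError, ValueError):
    """Schedule/dose bookkeeping disagrees beyond tolerance."""


class UnitError(GapDvhError, ValueError):
    """Mixing isoeffective doses with different alpha/beta tags or scales."""


class SessionGroupError(GapDvhError, ValueError):
    """Session-group fraction counts do not sum to the schedule's N."""


class EmptyStructureError(GapDvhError, ValueError):
    """A structure mask or DVH contains no volume."""


class CongruenceError(GapDvhError, ValueError):
    """Dose grid and structure mask shapes do not match."""


class GeometryError(GapDvhError, ValueError):
    """Contour plane does not map onto any dose-grid slice."""


class FormatError(GapDvhError, ValueError):
    """A DICOM or table file is malformed or of the wrong type."""


class CalendarError(GapDvhError, ValueError):
    """Treatment calendar is empty, unordered, or segments overlap."""


class SpecError(GapDvhError, ValueError):
    """A phantom specification is invalid."""
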