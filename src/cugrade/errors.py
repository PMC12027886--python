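"""Exception hierarchy.

Every stage of the grading pipeline raises a distinct error type so that
end-to-end callers (and the CLI exit-code mapping) can tell a data problem
from a configuration problem from a detection failure.
"""


class CugradeError(Exception):
    """Base class for all package errors."""


class ConfigurationError(CugradeError):
    """Invalid thresholds, model config, or scene specification."""


class RenderError(CugradeError):
    """A synthetic scene could not be rasterized (object outside the
    marker quadrilateral, or overlapping a marker)."""


class MarkerDetectionError(CugradeError):
    """Fewer than four fiducial markers found, or ambiguous corner
    assignment."""


class CalibrationError(CugradeError):
    """Degenerate marker geometry (zero inter-marker distance)."""


class SegmentationError(CugradeError):
    """No object pixels found inside the marker quadrilateral."""


class DecodeError(CugradeError):
    """Canvas background is not uniform across its corners."""


class CropOverflowError(CugradeError):
    """Rescaled object crop does not fit on the fixed-size canvas."""


class DataError(CugradeError):
    """Dataset labels or manifests outside the expected 7-grade set."""
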