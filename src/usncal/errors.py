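"""Exception hierarchy for the calibration toolkit."""


class UsncalError(Exception):
    """Base class for all package errors."""


class NearParallelLine(UsncalError):
    """Needle line is (numerically) parallel to the image plane.

    An in-plane needle never pierces the plane at a single pixel, so the
    observation is invalid for point-to-line calibration.
    """


class EmptyImage(UsncalError):
    """Zero-sized image passed where pixels are required."""


class BoundsRejection(UsncalError):
    """Predicted centroid fell outside the image bounds.

    Retriable: the caller should capture a new frame and localise again.
    """


class InvalidCount(UsncalError):
    """Requested a non-positive number of frames/samples."""


class SpecMismatch(UsncalError):
    """Architecture hyper-parameters do not produce the expected geometry."""


class EmptyDataset(UsncalError):
    """Training requested on an empty dataset."""


class ShapeMismatch(UsncalError):
    """Array shapes inconsistent with the model contract."""


class DegenerateConfiguration(UsncalError):
    """Source points are collinear/coincident: rotation not identifiable."""


class NonPositiveScale(UsncalError):
    """Anisotropic scale estimate collapsed to zero or negative."""


class InsufficientPairs(UsncalError):
    """Fewer point-line observations than the identifiability minimum."""


class DegenerateLines(UsncalError):
    """All needle lines (nearly) parallel: calibration unidentifiable."""


class EmptyPairs(UsncalError):
    """TRE requested over an empty observation set."""


class LengthMismatch(UsncalError):
    """Prediction and label lists differ in length."""


class TooFewRaters(UsncalError):
    """Rater-variability statistic needs at least two raters."""


class NonDecomposable(UsncalError):
    """3x3 block is not rotation x positive-diagonal (shear present)."""


class CaptureLoopAborted(UsncalError):
    """More than half of the captured frames were rejected by the localiser."""
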