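"""Localisation error metrics, rater variability and the capture loop.

Localisation accuracy is reported per image axis (lateral = across the
transducer face, axial = depth) as RMSE and MAE in pixels, converted to
millimetres with the pixel spacings extracted from a calibration.

The semi-automatic capture loop emulates the interactive workflow: freeze
a frame, localise the needle reflection automatically, pair the accepted
centroid with the tracked needle line, repeat for 12-15 frames (mostly
near the image corners), then solve the calibration.  An out-of-bounds
localisation rejects the frame and a new one is captured; a run in which
more than half of the frames are rejected aborts, signalling a broken
localiser.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Optional, Sequence, Tuple

import numpy as np

from .calibration import (
    CalibrationResults,
    PointLineCalibration,
    PointLinePair,
)
from .errors import BoundsRejection, CaptureLoopAborted, LengthMismatch, TooFewRaters
from .geometry import (
    PixelPoint,
    RigidScaledTransform,
    intersect_line_with_image_plane,
)
from .network import predict_centroid
from .phantom import (
    PhantomConfig,
    add_tracking_noise,
    in_plane_heading_deg,
    insertion_angle_deg,
    render_reflection_image,
    sample_needle_pose,
    _as_rng,
)

__all__ = [
    "AxisError",
    "AxisErrorReport",
    "axis_errors",
    "RaterStudy",
    "RaterVariability",
    "rater_variability",
    "SemiAutomaticResult",
    "run_semi_automatic_calibration",
]


# ---------------------------------------------------------------------------
# localisation error metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AxisError:
    """Errors along one image axis, in pixels and millimetres."""

    rmse_px: float
    mae_px: float
    mae_std_px: float
    rmse_mm: float
    mae_mm: float
    mae_std_mm: float


@dataclass(frozen=True)
class AxisErrorReport:
    lateral: AxisError
    axial: AxisError

    def summary(self) -> str:
        rows = [
            "Centroid localisation error",
            "===========================",
            f"{'metric':<18}{'lateral':>12}{'axial':>12}",
            f"{'RMSE px':<18}{self.lateral.rmse_px:>12.3f}{self.axial.rmse_px:>12.3f}",
            f"{'RMSE mm':<18}{self.lateral.rmse_mm:>12.3f}{self.axial.rmse_mm:>12.3f}",
            f"{'MAE px':<18}{self.lateral.mae_px:>12.3f}{self.axial.mae_px:>12.3f}",
            f"{'MAE std px':<18}{self.lateral.mae_std_px:>12.3f}{self.axial.mae_std_px:>12.3f}",
            f"{'MAE mm':<18}{self.lateral.mae_mm:>12.3f}{self.axial.mae_mm:>12.3f}",
            f"{'MAE std mm':<18}{self.lateral.mae_std_mm:>12.3f}{self.axial.mae_std_mm:>12.3f}",
        ]
        return "\n".join(rows)


def _axis(delta: np.ndarray, spacing: float) -> AxisError:
    rmse = float(np.sqrt(np.mean(delta**2)))
    mae = float(np.mean(np.abs(delta)))
    std = float(np.std(np.abs(delta)))  # population spread of |error|
    return AxisError(rmse, mae, std, rmse * spacing, mae * spacing, std * spacing)


def axis_errors(
    predictions: Sequence[PixelPoint],
    labels: Sequence[PixelPoint],
    spacings: Tuple[float, float],
) -> AxisErrorReport:
    """Per-axis RMSE/MAE between predicted and ground-truth centroids.

    ``spacings`` is ``(lateral, axial)`` mm per pixel, normally from
    :func:`~usncal.calibration.extract_pixel_spacings`.
    """
    if len(predictions) != len(labels) or len(labels) == 0:
        raise LengthMismatch("predictions and labels must have equal length >= 1")
    pred = np.array([[p.u, p.v] for p in predictions], dtype=float)
    lab = np.array([[p.u, p.v] for p in labels], dtype=float)
    delta = pred - lab
    return AxisErrorReport(
        lateral=_axis(delta[:, 0], spacings[0]),
        axial=_axis(delta[:, 1], spacings[1]),
    )


# ---------------------------------------------------------------------------
# inter-rater variability
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RaterStudy:
    """Manual centroid selections: array of shape (n_images, n_raters, 2).

    The trailing axis is (u, v); every image must carry the same number
    of raters (enforced by the rectangular array).
    """

    selections: np.ndarray
    image_width: int = 356
    image_height: int = 589

    def __post_init__(self) -> None:
        sel = np.asarray(self.selections, dtype=float)
        if sel.ndim != 3 or sel.shape[2] != 2:
            raise ValueError("selections must have shape (n_images, n_raters, 2)")
        object.__setattr__(self, "selections", sel)


@dataclass(frozen=True)
class RaterVariability:
    """Average per-image standard deviation across raters."""

    lateral_px: float
    axial_px: float
    lateral_unit: float  # on the per-axis [-1, 1] normalised coordinates
    axial_unit: float

    def __iter__(self) -> Iterator[float]:
        return iter((self.lateral_px, self.axial_px))


def rater_variability(study: RaterStudy) -> RaterVariability:
    """Inter-rater spread of manual centroid selections.

    For each image, the sample (ddof=1) standard deviation across raters
    is computed per axis; these are averaged over images.  The same
    statistic on unit-scaled coordinates is reported alongside.
    """
    sel = study.selections
    if sel.shape[1] < 2:
        raise TooFewRaters("need at least 2 raters")
    per_image = sel.std(axis=1, ddof=1)  # (n_images, 2)
    lat_px, axi_px = per_image.mean(axis=0)
    lat_unit = 2.0 * lat_px / (study.image_width - 1)
    axi_unit = 2.0 * axi_px / (study.image_height - 1)
    return RaterVariability(float(lat_px), float(axi_px), float(lat_unit), float(axi_unit))


# ---------------------------------------------------------------------------
# semi-automatic capture loop
# ---------------------------------------------------------------------------

@dataclass
class SemiAutomaticResult:
    """Outcome of one simulated freeze-localise-resume calibration run."""

    results: CalibrationResults
    comparison: dict            # errors vs the ground-truth transform
    pixel_spacings: Tuple[float, float]
    n_frames: int
    n_rejected: int
    n_attempts: int

    @property
    def rejected_fraction(self) -> float:
        return self.n_rejected / self.n_attempts if self.n_attempts else 0.0

    def summary(self) -> str:
        lines = [
            self.results.summary(),
            "",
            f"frames accepted       {self.n_frames}",
            f"frames rejected       {self.n_rejected} "
            f"({100 * self.rejected_fraction:.1f}% of {self.n_attempts} captures)",
            f"rotation error deg    {self.comparison['rotation_error_deg']:.4g}",
            f"translation error mm  {self.comparison['translation_error_mm']:.4g}",
            f"scale error % (lat)   {self.comparison['scale_error_pct_lateral']:.4g}",
            f"scale error % (axial) {self.comparison['scale_error_pct_axial']:.4g}",
        ]
        return "\n".join(lines)


def _corner_biased_target(
    config: PhantomConfig, rng: np.random.Generator
) -> PixelPoint:
    """Mostly corner-region targets, mirroring the recommended workflow."""
    W, H = config.image_width, config.image_height
    if rng.random() < 0.7:
        cu = 0.0 if rng.random() < 0.5 else 0.75
        cv = 0.0 if rng.random() < 0.5 else 0.75
        u = rng.uniform(cu * (W - 1), (cu + 0.25) * (W - 1))
        v = rng.uniform(cv * (H - 1), (cv + 0.25) * (H - 1))
    else:
        u = rng.uniform(0, W - 1)
        v = rng.uniform(0, H - 1)
    return PixelPoint(u, v)


def run_semi_automatic_calibration(
    model,
    T_gt: RigidScaledTransform,
    n_frames: int,
    config: PhantomConfig,
    rng=None,
) -> SemiAutomaticResult:
    """Simulate the freeze-localise-resume calibration workflow.

    Each capture renders a frame from a corner-biased oblique insertion,
    runs the localiser, and on a bounds rejection discards the frame and
    captures a new one.  Accepted centroids are paired with the
    tracking-noisy needle line; after ``n_frames`` acceptances the
    calibration is solved and compared to the ground truth.

    ``model=None`` substitutes perfect geometric labels (rounded to the
    pixel grid) for the network, isolating the calibration stage.

    Raises
    ------
    CaptureLoopAborted
        When more than half of the captured frames are rejected.
    """
    rng = _as_rng(rng)
    pairs = []
    n_rejected = 0
    n_attempts = 0
    max_attempts = max(4 * n_frames, n_frames + 10)
    while len(pairs) < n_frames and n_attempts < max_attempts:
        n_attempts += 1
        target = _corner_biased_target(config, rng)
        pose = sample_needle_pose(T_gt, target, config, rng)
        label = intersect_line_with_image_plane(T_gt, pose)
        if not label.in_bounds(config.image_width, config.image_height):
            continue  # expert would not freeze a frame without a reflection
        noisy = add_tracking_noise(pose, config, rng)
        if model is None:
            centroid = label  # perfect localiser: exact geometric label
        else:
            angle = insertion_angle_deg(T_gt, pose)
            heading = in_plane_heading_deg(T_gt, pose)
            image = render_reflection_image(label, angle, config, rng, heading=heading)
            try:
                centroid = predict_centroid(model, image)
            except BoundsRejection:
                n_rejected += 1
                continue
        pairs.append(PointLinePair(centroid, noisy))
        if n_rejected > max(n_attempts - n_rejected, 0) and n_rejected > n_frames:
            break
    if len(pairs) < n_frames or n_rejected / n_attempts > 0.5:
        raise CaptureLoopAborted(
            f"{n_rejected}/{n_attempts} captures rejected; localiser unusable"
        )
    results = PointLineCalibration(pairs).fit()
    return SemiAutomaticResult(
        results=results,
        comparison=results.compare_to(T_gt),
        pixel_spacings=results.pixel_spacings,
        n_frames=len(pairs),
        n_rejected=n_rejected,
        n_attempts=n_attempts,
    )
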