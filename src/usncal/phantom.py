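"""Synthetic water-bath phantom: annotated needle-reflection frames.

Emulates the data-collection procedure for needle-based probe calibration:
a tracked needle is inserted obliquely through the ultrasound image plane
of a water bath, producing a bright cross-sectional reflection on a
near-black speckled background.  Each generated frame carries

* the rendered 8-bit B-mode image,
* the ground-truth centroid label, computed **geometrically** by applying
  the inverse ground-truth calibration to the needle pose (never read back
  from rendered pixels),
* the noiseless needle line and a copy perturbed by tracker noise at the
  manufacturer-reported level (1.2 mm RMS position, 0.5 deg RMS
  orientation).

The reflection model is a parametric bright ellipse plus a decaying
reverberation tail, not a wave-propagation simulator: reflection size and
blur grow towards the far field (deep portion of the image), and the blob
is elongated along the needle's in-plane heading by ``1/sin`` of the
insertion angle, reproducing the phenomenology the localisation network
must cope with.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np

from .errors import InvalidCount
from .geometry import (
    NeedleLine,
    PixelPoint,
    RigidScaledTransform,
    intersect_line_with_image_plane,
    lift_pixel_to_tracker,
)

__all__ = [
    "PhantomConfig",
    "AnnotatedFrame",
    "make_ground_truth_calibration",
    "sample_needle_pose",
    "add_tracking_noise",
    "render_reflection_image",
    "generate_dataset",
    "insertion_angle_deg",
    "in_plane_heading_deg",
    "blob_semi_axes",
    "intensity_weighted_centroid",
]

RngLike = Union[int, np.random.Generator, None]


def _as_rng(rng: RngLike) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry, reflection and noise parameters of the simulated phantom.

    Defaults reproduce the native acquisition geometry: a 356x589 px frame
    at 6 cm depth with pixel spacings 0.097 mm laterally and 0.102 mm
    axially, oblique insertions 20-70 deg from the image plane, and
    tracking noise of 1.2 mm RMS / 0.5 deg RMS.
    """

    image_width: int = 356
    image_height: int = 589
    depth_cm: float = 6.0
    spacing_axial: float = 0.102    # mm per pixel along v (depth)
    spacing_lateral: float = 0.097  # mm per pixel along u
    reflection_base_radius: float = 6.0  # px, near-field semi-minor axis
    farfield_gain: float = 1.0      # fractional size growth over full depth
    speckle_scale: float = 6.0      # mean background intensity (8-bit units)
    insertion_angle_range: Tuple[float, float] = (20.0, 70.0)  # deg from plane
    tip_distance_range_mm: Tuple[float, float] = (10.0, 60.0)
    tracking_noise_pos_mm: float = 1.2   # RMS tip displacement norm
    tracking_noise_rot_deg: float = 0.5  # RMS direction rotation angle
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.insertion_angle_range
        if not (0.0 < lo <= hi < 90.0):
            raise ValueError("insertion_angle_range must lie inside (0, 90) deg")
        for name in (
            "image_width", "image_height", "depth_cm", "spacing_axial",
            "spacing_lateral", "reflection_base_radius", "speckle_scale",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.farfield_gain < 0 or self.tracking_noise_pos_mm < 0 or self.tracking_noise_rot_deg < 0:
            raise ValueError("gains and noise magnitudes must be non-negative")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class AnnotatedFrame:
    """One simulated capture: image, geometric label and tracked poses."""

    image: np.ndarray            # uint8, (H, W)
    label: PixelPoint            # ground-truth centroid, original pixels
    pose: NeedleLine             # noiseless tracked needle
    noisy_pose: NeedleLine       # tracker noise applied
    insertion_angle: float = 0.0  # deg from image plane
    heading: float = 0.0          # deg, in-plane direction of the shaft
    frame_id: int = 0


# ---------------------------------------------------------------------------
# ground-truth calibration and needle poses
# ---------------------------------------------------------------------------

def make_ground_truth_calibration(
    config: PhantomConfig, rng: RngLike = None
) -> RigidScaledTransform:
    """Random plausible image-to-tracker calibration.

    Stands in for an expert's careful manual calibration: a uniformly
    random rotation, scales ``(spacing_lateral, spacing_axial, mean)``
    (the elevational scale is unobservable and fixed to the in-plane
    mean), and a translation placing the image within 500 mm of the
    tracker origin.  Deterministic under a fixed seed.
    """
    rng = _as_rng(rng)
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    rotation = np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
        [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
        [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
    ])
    s_z = 0.5 * (config.spacing_lateral + config.spacing_axial)
    scales = (config.spacing_lateral, config.spacing_axial, s_z)
    translation = rng.uniform(-250.0, 250.0, size=3)
    return RigidScaledTransform.from_parts(rotation, scales, translation)


def sample_needle_pose(
    T_gt: RigidScaledTransform,
    target_pixel: PixelPoint,
    config: PhantomConfig,
    rng: RngLike = None,
) -> NeedleLine:
    """Tracked needle line piercing the image plane exactly at a pixel.

    The insertion angle (between the needle axis and the image plane) is
    uniform over ``config.insertion_angle_range``; the in-plane azimuth is
    uniform; the tip sits 10-60 mm from the plane on a random side.
    """
    rng = _as_rng(rng)
    if not target_pixel.in_bounds(config.image_width, config.image_height):
        raise ValueError("target pixel out of image bounds")
    pierce = lift_pixel_to_tracker(T_gt, target_pixel)
    R = T_gt.rotation
    normal = R[:, 2]
    azimuth = rng.uniform(0.0, 2.0 * np.pi)
    in_plane = np.cos(azimuth) * R[:, 0] + np.sin(azimuth) * R[:, 1]
    theta = np.radians(rng.uniform(*config.insertion_angle_range))
    direction = np.cos(theta) * in_plane + np.sin(theta) * normal
    h = rng.uniform(*config.tip_distance_range_mm)
    side = 1.0 if rng.random() < 0.5 else -1.0
    tip = pierce - side * (h / np.sin(theta)) * direction
    return NeedleLine(tip, direction)


def add_tracking_noise(
    line: NeedleLine, config: PhantomConfig, rng: RngLike = None
) -> NeedleLine:
    """Perturb a needle line at the tracker's reported noise level.

    Tip: isotropic Gaussian with RMS displacement *norm* equal to
    ``tracking_noise_pos_mm`` (per-component sigma = RMS / sqrt(3)).
    Direction: rotated about a uniformly random axis by a zero-mean
    Gaussian angle with RMS ``tracking_noise_rot_deg``.
    """
    rng = _as_rng(rng)
    if config.tracking_noise_pos_mm == 0.0 and config.tracking_noise_rot_deg == 0.0:
        return line
    tip = line.tip + rng.normal(
        0.0, config.tracking_noise_pos_mm / np.sqrt(3.0), size=3
    )
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = np.radians(rng.normal(0.0, config.tracking_noise_rot_deg))
    k = axis
    d = line.direction
    # Rodrigues rotation of the direction about the random axis
    d_rot = (
        d * np.cos(angle)
        + np.cross(k, d) * np.sin(angle)
        + k * np.dot(k, d) * (1.0 - np.cos(angle))
    )
    return NeedleLine(tip, d_rot)


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

#: Peak 8-bit intensity of the reflection blob.
BLOB_PEAK = 230.0
#: Threshold separating reflection from speckle when computing moments.
CENTROID_THRESHOLD = 60.0


def blob_semi_axes(
    v: float, insertion_angle: float, config: PhantomConfig
) -> Tuple[float, float]:
    """(semi-major, semi-minor) px of the reflection at image row ``v``.

    The minor axis grows linearly towards the far field; the major axis is
    the minor axis elongated by ``1 / sin(insertion angle)`` because an
    oblique shaft sweeps a longer in-plane footprint.
    """
    minor = config.reflection_base_radius * (
        1.0 + config.farfield_gain * v / config.image_height
    )
    major = minor / np.sin(np.radians(insertion_angle))
    return float(major), float(minor)


def render_reflection_image(
    centroid: PixelPoint,
    insertion_angle: float,
    config: PhantomConfig,
    rng: RngLike = None,
    heading: Optional[float] = None,
) -> np.ndarray:
    """Render one 8-bit frame: speckle background + needle reflection.

    The background is dim multiplicative speckle (gamma-distributed, mean
    ``speckle_scale`` < 15/255 of full scale).  The reflection is a
    Gaussian-profile ellipse centred at ``centroid`` with semi-axes from
    :func:`blob_semi_axes`, rotated to the in-plane ``heading`` (drawn
    from ``rng`` when not given), followed by a weak decaying reverberation
    tail directly below.  The intensity-weighted centroid of the
    above-threshold region stays within ~1.5 px of the request for
    interior centroids.
    """
    rng = _as_rng(rng)
    H, W = config.image_height, config.image_width
    if not centroid.in_bounds(W, H):
        raise ValueError("centroid out of image bounds")
    if heading is None:
        heading = rng.uniform(0.0, 360.0)

    img = rng.gamma(2.0, config.speckle_scale / 2.0, size=(H, W)).astype(np.float32)

    major, minor = blob_semi_axes(centroid.v, insertion_angle, config)
    # Gaussian sigmas chosen so intensity falls to ~13% of peak at the semi-axes
    sig_a, sig_b = major / 2.0, minor / 2.0
    phi = np.radians(heading)
    cos_p, sin_p = np.cos(phi), np.sin(phi)

    def _add_blob(cu: float, cv: float, amp: float, blur: float = 1.0) -> None:
        sa, sb = sig_a * blur, sig_b * blur
        r = 4.0 * max(sa, sb)
        u0, u1 = max(0, int(cu - r)), min(W, int(cu + r) + 1)
        v0, v1 = max(0, int(cv - r)), min(H, int(cv + r) + 1)
        if u0 >= u1 or v0 >= v1:
            return
        uu, vv = np.meshgrid(
            np.arange(u0, u1, dtype=np.float32),
            np.arange(v0, v1, dtype=np.float32),
        )
        du, dv = uu - cu, vv - cv
        x = cos_p * du + sin_p * dv
        y = -sin_p * du + cos_p * dv
        img[v0:v1, u0:u1] += amp * np.exp(
            -0.5 * ((x / sa) ** 2 + (y / sb) ** 2)
        )

    _add_blob(centroid.u, centroid.v, BLOB_PEAK)
    # reverberation ghosts: below the reflection, fading and blurring out;
    # amplitudes sit below CENTROID_THRESHOLD so moments stay on the blob
    tail_spacing = 2.5 * minor
    for k, amp_frac in enumerate((0.15, 0.07), start=1):
        _add_blob(
            centroid.u,
            centroid.v + k * tail_spacing,
            BLOB_PEAK * amp_frac,
            blur=1.0 + 0.3 * k,
        )

    return np.clip(img, 0.0, 255.0).astype(np.uint8)


def intensity_weighted_centroid(
    image: np.ndarray, threshold: float = CENTROID_THRESHOLD
) -> PixelPoint:
    """First moment of the above-threshold (reflection) region."""
    img = np.asarray(image, dtype=float)
    mask = img > threshold
    if not mask.any():
        raise ValueError("no pixels above threshold")
    vv, uu = np.nonzero(mask)
    w = img[vv, uu]
    return PixelPoint(float(np.average(uu, weights=w)), float(np.average(vv, weights=w)))


# ---------------------------------------------------------------------------
# pose geometry helpers
# ---------------------------------------------------------------------------

def insertion_angle_deg(T: RigidScaledTransform, line: NeedleLine) -> float:
    """Angle (deg) between the needle axis and the image plane of ``T``."""
    s = abs(float(np.dot(line.direction, T.plane_normal)))
    return float(np.degrees(np.arcsin(np.clip(s, 0.0, 1.0))))


def in_plane_heading_deg(T: RigidScaledTransform, line: NeedleLine) -> float:
    """In-plane heading (deg, pixel axes) of the needle's image-frame shadow."""
    d_img = T.inverse_matrix()[:3, :3] @ line.direction
    return float(np.degrees(np.arctan2(d_img[1], d_img[0])))


# ---------------------------------------------------------------------------
# dataset generation
# ---------------------------------------------------------------------------

def sample_calibration_observations(
    T_gt: RigidScaledTransform,
    n: int,
    config: PhantomConfig,
    rng: RngLike = None,
):
    """Geometry-only observations for calibration studies.

    Returns a list of ``(label, pose, noisy_pose)`` triples with centroid
    targets stratified over the image (corners represented) and oblique
    insertions; no images are rendered.
    """
    if n < 1:
        raise InvalidCount("n must be >= 1")
    rng = _as_rng(rng)
    out = []
    for i in range(n):
        target = _stratified_target(i, config, rng)
        pose = sample_needle_pose(T_gt, target, config, rng)
        label = intersect_line_with_image_plane(T_gt, pose)
        noisy = add_tracking_noise(pose, config, rng)
        out.append((label, pose, noisy))
    return out


_GRID = 4  # stratification grid: centroids cover a 4x4 partition of the image


def _stratified_target(
    i: int, config: PhantomConfig, rng: np.random.Generator
) -> PixelPoint:
    """Uniform draw within cell ``i mod 16`` of the 4x4 image partition."""
    cell = i % (_GRID * _GRID)
    cu, cv = cell % _GRID, cell // _GRID
    u = rng.uniform(cu * (config.image_width - 1) / _GRID,
                    (cu + 1) * (config.image_width - 1) / _GRID)
    v = rng.uniform(cv * (config.image_height - 1) / _GRID,
                    (cv + 1) * (config.image_height - 1) / _GRID)
    return PixelPoint(u, v)


def generate_dataset(
    n_frames: int,
    config: PhantomConfig,
    rng: RngLike = None,
    render: bool = True,
) -> Tuple[List[AnnotatedFrame], RigidScaledTransform]:
    """Generate an annotated dataset plus its ground-truth calibration.

    Centroid targets are stratified over a 4x4 grid so corners and edges
    are represented.  Labels are produced by intersecting the (noiseless)
    tracked line with the image plane via the inverse calibration — the
    same construction used to annotate real acquisitions — and frames
    whose label would fall out of bounds are resampled, so the requested
    count is exact.  Frame ``i`` draws from a deterministic substream of
    the dataset seed, making generation reproducible and order-independent.

    Set ``render=False`` to skip image synthesis when only the geometry is
    needed (e.g. calibration-only studies).
    """
    if n_frames < 1:
        raise InvalidCount("n_frames must be >= 1")
    rng = _as_rng(config.seed if rng is None else rng)
    base = int(rng.integers(0, 2**31 - 1))
    T_gt = make_ground_truth_calibration(config, np.random.default_rng([base, 2**31]))

    frames: List[AnnotatedFrame] = []
    for i in range(n_frames):
        sub = np.random.default_rng([base, i])
        for _attempt in range(100):
            target = _stratified_target(i, config, sub)
            pose = sample_needle_pose(T_gt, target, config, sub)
            label = intersect_line_with_image_plane(T_gt, pose)
            if label.in_bounds(config.image_width, config.image_height):
                break
        else:  # pragma: no cover - construction places labels in bounds
            raise RuntimeError("could not sample an in-bounds frame")
        noisy = add_tracking_noise(pose, config, sub)
        angle = insertion_angle_deg(T_gt, pose)
        heading = in_plane_heading_deg(T_gt, pose)
        if render:
            image = render_reflection_image(label, angle, config, sub, heading=heading)
        else:
            image = np.zeros((0, 0), dtype=np.uint8)
        frames.append(
            AnnotatedFrame(
                image=image,
                label=label,
                pose=pose,
                noisy_pose=noisy,
                insertion_angle=angle,
                heading=heading,
                frame_id=i,
            )
        )
    return frames, T_gt
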