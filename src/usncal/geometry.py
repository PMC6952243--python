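"""Homogeneous-transform, line and plane-line intersection primitives.

Conventions
-----------
Pixel coordinates are 0-based ``(u, v) = (column, row)``: ``u`` is the
lateral axis (across the transducer face) and ``v`` is the axial axis
(depth increases with ``v``).  At the native 6 cm linear-probe geometry
``u`` spans ``[0, 355]`` and ``v`` spans ``[0, 588]``; pixel centres sit at
integer coordinates.

The image plane is the ``{z = 0}`` plane of the image frame.  A probe
calibration is a 4x4 homogeneous transform whose 3x3 block factors as
``rotation x diag(s_x, s_y, s_z)`` with the per-axis scales carrying the
mm-per-pixel spacings; a pixel ``(u, v)`` maps to the tracker frame as
``T @ (u, v, 0, 1)``.  The elevational (z) scale is unobservable from
planar data and is carried only so the matrix stays invertible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np

from .errors import NearParallelLine, NonDecomposable

__all__ = [
    "RigidScaledTransform",
    "NeedleLine",
    "PixelPoint",
    "lift_pixel_to_tracker",
    "intersect_line_with_image_plane",
    "point_to_line_distance",
    "closest_point_on_line",
]

#: |z-component| of the unit direction (image frame) below which a needle is
#: treated as in-plane and rejected.
PARALLEL_TOL = 1e-8

_DECOMP_TOL = 1e-9


@dataclass(frozen=True)
class PixelPoint:
    """A pixel coordinate: ``u`` = column (lateral), ``v`` = row (axial)."""

    u: float
    v: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.u) and np.isfinite(self.v)):
            raise ValueError("pixel coordinates must be finite")

    def as_array(self) -> np.ndarray:
        return np.array([self.u, self.v], dtype=float)

    def in_bounds(self, width: int, height: int) -> bool:
        return 0 <= self.u <= width - 1 and 0 <= self.v <= height - 1


@dataclass(frozen=True)
class NeedleLine:
    """Tracked needle axis: tip position (mm) plus unit direction.

    The infinite line is ``{tip + t * direction}``; the direction is
    normalised on construction and must be non-degenerate.
    """

    tip: np.ndarray
    direction: np.ndarray

    def __init__(self, tip, direction) -> None:
        tip = np.asarray(tip, dtype=float).reshape(3)
        direction = np.asarray(direction, dtype=float).reshape(3)
        norm = float(np.linalg.norm(direction))
        if not np.isfinite(norm) or norm < 1e-12:
            raise ValueError("needle direction must be a non-zero 3-vector")
        object.__setattr__(self, "tip", tip)
        object.__setattr__(self, "direction", direction / norm)

    def point_at(self, t: float) -> np.ndarray:
        return self.tip + t * self.direction

    def transformed(self, matrix: np.ndarray) -> "NeedleLine":
        """Apply a rigid 4x4 transform to the line."""
        matrix = np.asarray(matrix, dtype=float)
        tip = matrix[:3, :3] @ self.tip + matrix[:3, 3]
        direction = matrix[:3, :3] @ self.direction
        return NeedleLine(tip, direction)


class RigidScaledTransform:
    """4x4 homogeneous map whose 3x3 block is rotation x positive diagonal.

    For calibration use the diagonal carries the anisotropic mm-per-pixel
    scales ``(s_x, s_y, s_z)`` = (lateral, axial, elevational).

    Parameters
    ----------
    matrix
        4x4 homogeneous matrix with last row ``(0, 0, 0, 1)`` and an
        invertible 3x3 block factoring as rotation x diag(scales > 0).
    """

    __slots__ = ("_matrix",)

    def __init__(self, matrix) -> None:
        matrix = np.array(matrix, dtype=float).reshape(4, 4)
        if not np.allclose(matrix[3], [0.0, 0.0, 0.0, 1.0], atol=1e-12):
            raise ValueError("last row must be (0, 0, 0, 1)")
        block = matrix[:3, :3]
        scales = np.linalg.norm(block, axis=0)
        if np.any(scales <= 0) or not np.all(np.isfinite(scales)):
            raise ValueError("3x3 block must have positive column norms")
        rot = block / scales
        if not np.allclose(rot.T @ rot, np.eye(3), atol=1e-8):
            raise ValueError("3x3 block must factor as rotation x diag(scales)")
        if np.linalg.det(rot) < 0:
            raise ValueError("rotation factor must have det +1")
        self._matrix = matrix

    # -- constructors -----------------------------------------------------
    @classmethod
    def from_parts(cls, rotation, scales, translation) -> "RigidScaledTransform":
        rotation = np.asarray(rotation, dtype=float).reshape(3, 3)
        scales = np.asarray(scales, dtype=float).reshape(3)
        translation = np.asarray(translation, dtype=float).reshape(3)
        m = np.eye(4)
        m[:3, :3] = rotation @ np.diag(scales)
        m[:3, 3] = translation
        return cls(m)

    @classmethod
    def identity(cls) -> "RigidScaledTransform":
        return cls(np.eye(4))

    # -- views ------------------------------------------------------------
    @property
    def matrix(self) -> np.ndarray:
        return self._matrix.copy()

    @property
    def scales(self) -> np.ndarray:
        """Per-axis scales: column norms of the 3x3 block (exact for R @ S)."""
        return np.linalg.norm(self._matrix[:3, :3], axis=0)

    @property
    def rotation(self) -> np.ndarray:
        return self._matrix[:3, :3] / self.scales

    @property
    def translation(self) -> np.ndarray:
        return self._matrix[:3, 3].copy()

    @property
    def plane_normal(self) -> np.ndarray:
        """Unit normal of the image plane {z=0} in tracker coordinates."""
        return self.rotation[:, 2]

    def inverse_matrix(self) -> np.ndarray:
        return np.linalg.inv(self._matrix)

    def compose_left(self, rigid: np.ndarray) -> "RigidScaledTransform":
        """Return G @ T for a rigid 4x4 ``G`` (used by equivariance tests)."""
        return RigidScaledTransform(np.asarray(rigid, dtype=float) @ self._matrix)

    def __repr__(self) -> str:  # pragma: no cover
        s = self.scales
        return (
            f"RigidScaledTransform(scales=({s[0]:.4g}, {s[1]:.4g}, {s[2]:.4g}), "
            f"t={np.array2string(self.translation, precision=2)})"
        )


def lift_pixel_to_tracker(T: RigidScaledTransform, p) -> np.ndarray:
    """Map pixel ``(u, v)`` to its 3D tracker-frame point on the image plane.

    The image-plane elevation coordinate is fixed at 0:
    ``(u, v) -> T @ (u, v, 0, 1)``.
    """
    if isinstance(p, PixelPoint):
        u, v = p.u, p.v
    else:
        u, v = float(p[0]), float(p[1])
    h = T.matrix @ np.array([u, v, 0.0, 1.0])
    return h[:3]


def intersect_line_with_image_plane(T: RigidScaledTransform, line: NeedleLine) -> PixelPoint:
    """Pixel coordinates where a tracked needle pierces the image plane of T.

    Maps the line into the image frame with the inverse calibration and
    solves for the parameter where its elevation coordinate vanishes — the
    inverse-calibration label construction used to annotate frames.

    Raises
    ------
    NearParallelLine
        If the elevation component of the (image-frame, normalised)
        direction is below tolerance: the needle lies in the image plane.
    """
    inv = T.inverse_matrix()
    tip_img = inv[:3, :3] @ line.tip + inv[:3, 3]
    dir_img = inv[:3, :3] @ line.direction
    dir_unit = dir_img / np.linalg.norm(dir_img)
    if abs(dir_unit[2]) < PARALLEL_TOL:
        raise NearParallelLine(
            "needle direction is within tolerance of the image plane; "
            "capture an oblique (out-of-plane) insertion"
        )
    t = -tip_img[2] / dir_img[2]
    hit = tip_img + t * dir_img
    return PixelPoint(float(hit[0]), float(hit[1]))


def closest_point_on_line(x, line: NeedleLine) -> np.ndarray:
    """Foot of the perpendicular from ``x`` to the infinite needle axis."""
    x = np.asarray(x, dtype=float).reshape(3)
    t = float(np.dot(x - line.tip, line.direction))
    return line.point_at(t)


def point_to_line_distance(x, line: NeedleLine) -> float:
    """Minimal Euclidean distance (mm) from a point to the needle axis."""
    x = np.asarray(x, dtype=float).reshape(3)
    return float(np.linalg.norm(x - closest_point_on_line(x, line)))


def require_rotation_times_diag(block: np.ndarray, tol: float = _DECOMP_TOL) -> np.ndarray:
    """Column norms of a 3x3 block, verified against its singular values.

    For ``R @ diag(s)`` the singular values equal the column norms; a
    disagreement beyond ``tol`` indicates shear and raises
    :class:`~usncal.errors.NonDecomposable`.
    """
    block = np.asarray(block, dtype=float).reshape(3, 3)
    col_norms = np.linalg.norm(block, axis=0)
    sv = np.linalg.svd(block, compute_uv=False)
    if not np.allclose(np.sort(sv), np.sort(col_norms), atol=max(tol, tol * sv.max())):
        raise NonDecomposable(
            "singular values and column norms disagree: block is not "
            "rotation x positive diagonal"
        )
    return col_norms


def rotation_angle_deg(R: np.ndarray) -> float:
    """Rotation angle (degrees) of a 3x3 rotation matrix."""
    c = (np.trace(R) - 1.0) / 2.0
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))
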