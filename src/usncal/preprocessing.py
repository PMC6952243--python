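"""Frame and label preprocessing for the centroid-regression network.

Raw B-mode frames (8-bit grayscale, natively 356x589 at 6 cm depth) are
resized to 128x128 with bilinear interpolation and normalised to [0, 1].
Labels stay in the coordinates of the *original* frame: each axis is mapped
affinely from the integer range ``[0, extent-1]`` to the continuous range
``[-1, 1]`` (at native geometry: ``[0, 355]`` laterally, ``[0, 588]``
axially).  Network outputs are mapped back with the inverse affine and
rounded half-away-from-zero to integer pixels, then bounds-checked; an
out-of-bounds prediction is a retriable rejection ("capture a new frame").

The per-axis ``extent-1`` endpoints generalise the native ranges so frames
recorded at other imaging depths (4-8 cm, hence other heights) share one
code path.
"""

from __future__ import annotations

from typing import Tuple

import numpy as np
from skimage.transform import resize as _sk_resize

from .errors import BoundsRejection, EmptyImage
from .geometry import PixelPoint

__all__ = [
    "MODEL_INPUT_SIZE",
    "resize_to_model",
    "scale_label_to_unit",
    "unscale_prediction",
    "bounds_check",
    "round_half_away_from_zero",
]

MODEL_INPUT_SIZE = 128


def resize_to_model(image: np.ndarray) -> np.ndarray:
    """Resize an 8-bit grayscale frame to 128x128 and normalise to [0, 1].

    Bilinear interpolation, no aspect-ratio preservation (the native
    356x589 frame maps onto the square model input), then division by 255.
    """
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError(f"expected a 2D grayscale image, got shape {image.shape}")
    if image.size == 0:
        raise EmptyImage("cannot resize an empty image")
    out = _sk_resize(
        image.astype(np.float32),
        (MODEL_INPUT_SIZE, MODEL_INPUT_SIZE),
        order=1,
        mode="edge",
        anti_aliasing=False,
        preserve_range=True,
    )
    return (out / 255.0).astype(np.float32)


def scale_label_to_unit(p, width: int, height: int) -> Tuple[float, float]:
    """Map a pixel label onto the network's [-1, 1]^2 output range.

    Affine per axis: ``0 -> -1`` and ``extent-1 -> +1`` (lateral extent =
    width, axial extent = height).
    """
    if width < 2 or height < 2:
        raise ValueError("image extents must be at least 2 pixels")
    if isinstance(p, PixelPoint):
        u, v = p.u, p.v
    else:
        u, v = float(p[0]), float(p[1])
    return 2.0 * u / (width - 1) - 1.0, 2.0 * v / (height - 1) - 1.0


def round_half_away_from_zero(x: np.ndarray) -> np.ndarray:
    """Symmetric deterministic rounding: 0.5 -> 1, -0.5 -> -1."""
    x = np.asarray(x, dtype=float)
    return np.copysign(np.floor(np.abs(x) + 0.5), x)


def unscale_prediction(q, width: int, height: int) -> PixelPoint:
    """Map a network output in unit coordinates back to integer pixels.

    Inverse affine of :func:`scale_label_to_unit` followed by
    half-away-from-zero rounding.  Out-of-range inputs are allowed here;
    bounds are enforced separately by :func:`bounds_check`.
    """
    if width < 2 or height < 2:
        raise ValueError("image extents must be at least 2 pixels")
    qx, qy = float(q[0]), float(q[1])
    u = (qx + 1.0) * (width - 1) / 2.0
    v = (qy + 1.0) * (height - 1) / 2.0
    u, v = round_half_away_from_zero(np.array([u, v]))
    return PixelPoint(int(u), int(v))


def bounds_check(p: PixelPoint, width: int, height: int) -> PixelPoint:
    """Accept a pixel iff it lies inside the original image bounds.

    Raises
    ------
    BoundsRejection
        Retriable rejection: the caller must capture a new frame.  Bounds
        are inclusive: ``(width-1, height-1)`` is accepted.
    """
    if not p.in_bounds(width, height):
        raise BoundsRejection(
            f"predicted centroid ({p.u}, {p.v}) outside image bounds "
            f"{width}x{height}; capture a new frame"
        )
    return p
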