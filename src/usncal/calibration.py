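"""Procrustean point-to-line probe calibration with anisotropic scaling.

The calibration problem: given pixel centroids :math:`p_i = (u_i, v_i, 0)`
of out-of-plane needle reflections and the corresponding tracked needle
axes :math:`L_i` (tip + unit direction in the tracker frame), find the
homogeneous map :math:`T = (R, S, t)` — rotation, positive anisotropic
scales (the mm-per-pixel spacings) and translation — minimising the RMS
point-to-line distance

.. math:: \\mathrm{TRE}(T)^2 = \\frac{1}{n} \\sum_i d(R S p_i + t,\\ L_i)^2 .

It is solved ICP-style: map the pixel points with the current estimate,
replace each line by the closest point on it, solve the resulting
point-to-point anisotropic Procrustes problem in closed alternating form,
and repeat.  Both loops are monotone: the inner alternation never
increases its objective, the outer loop never increases the TRE.

Because all pixel points lie in the image plane (elevation 0), the
elevational scale is unidentifiable and is fixed to the mean of the two
in-plane scales; it affects neither the TRE nor the extracted spacings.

The public surface follows the model/results idiom:
``PointLineCalibration(pairs).fit()`` returns a
:class:`CalibrationResults` with the transform, the TRE, iteration
diagnostics and a ``summary()`` table.  :func:`calibrate` is the
functional wrapper.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .errors import (
    DegenerateConfiguration,
    DegenerateLines,
    EmptyPairs,
    InsufficientPairs,
    NonPositiveScale,
)
from .geometry import (
    NeedleLine,
    PixelPoint,
    RigidScaledTransform,
    closest_point_on_line,
    point_to_line_distance,
    require_rotation_times_diag,
    rotation_angle_deg,
)

__all__ = [
    "PointLinePair",
    "CalibrationResults",
    "PointLineCalibration",
    "MIN_PAIRS",
    "solve_anisotropic_procrustes",
    "calibrate",
    "compute_tre",
    "extract_pixel_spacings",
    "tre_vs_n_pairs",
]

#: Identifiability floor: 8 free parameters (3 rotation + 3 translation +
#: 2 in-plane scales), 2 constraints per point-line pair, plus slack
#: against near-degenerate geometry.
MIN_PAIRS = 6

_PARALLEL_LINES_DEG = 1.0


@dataclass(frozen=True)
class PointLinePair:
    """One calibration observation: pixel centroid + tracked needle axis."""

    point: PixelPoint
    line: NeedleLine


# ---------------------------------------------------------------------------
# inner solver: anisotropic point-to-point Procrustes
# ---------------------------------------------------------------------------

def solve_anisotropic_procrustes(
    sources,
    targets,
    fixed_elevation_scale: bool = False,
    tol: float = 1e-12,
    max_iter: int = 200,
) -> RigidScaledTransform:
    """Least-squares fit of ``q_i ~ R S p_i + t`` with anisotropic S.

    Alternating exact minimisation over demeaned sets: (a) given S, the
    rotation from the det-corrected SVD of the cross-covariance (Kabsch,
    with the sign flip applied to the column of the smallest singular
    value); (b) given R, each scale in closed form
    ``s_k = sum_i p~_ik (R^T q~_i)_k / sum_i p~_ik^2``; (c) the
    translation from the centroids.  The objective is non-increasing
    across iterations.

    With ``fixed_elevation_scale`` (or when every source elevation is 0)
    the z-scale is unidentifiable and is set to the mean of the in-plane
    scales after convergence.

    Raises
    ------
    DegenerateConfiguration
        Fewer than 4 correspondences, collinear/coincident sources, or an
        identifiable axis with zero source variance.
    NonPositiveScale
        A fitted identifiable scale collapsed to <= 0.
    """
    P = np.asarray(sources, dtype=float).reshape(-1, 3)
    Q = np.asarray(targets, dtype=float).reshape(-1, 3)
    if P.shape != Q.shape or len(P) < 4:
        raise DegenerateConfiguration("need >= 4 source/target correspondences")
    p_bar, q_bar = P.mean(axis=0), Q.mean(axis=0)
    Pt, Qt = P - p_bar, Q - q_bar

    planar = bool(np.all(np.abs(Pt[:, 2]) < 1e-12))
    fixed_z = fixed_elevation_scale or planar
    if np.linalg.matrix_rank(Pt, tol=1e-9 * max(1.0, np.abs(Pt).max())) < 2:
        raise DegenerateConfiguration("source points are collinear or coincident")
    ssq = (Pt ** 2).sum(axis=0)
    free_axes = [0, 1] if fixed_z else [0, 1, 2]
    if any(ssq[k] < 1e-12 for k in free_axes):
        raise DegenerateConfiguration(
            "zero source variance on an identifiable axis"
        )

    # global-ratio scale init keeps the first rotation solve well-conditioned
    s0 = np.linalg.norm(Qt) / max(np.linalg.norm(Pt), 1e-30)
    S = np.array([s0, s0, s0])
    obj_prev = np.inf
    R = np.eye(3)
    for _ in range(max_iter):
        A = Pt * S  # scaled, demeaned sources
        U, sig, Vt = np.linalg.svd(A.T @ Qt)
        D = np.eye(3)
        if np.linalg.det(U) * np.linalg.det(Vt) < 0:
            D[2, 2] = -1.0  # flip the column of the smallest singular value
        R = Vt.T @ D @ U.T
        B = Qt @ R  # = (R^T q~)_i rows
        for k in free_axes:
            S[k] = float(Pt[:, k] @ B[:, k] / ssq[k])
        if fixed_z:
            S[2] = 0.5 * (S[0] + S[1])
        obj = float(np.sum(((Pt * S) @ R.T - Qt) ** 2))
        if np.isfinite(obj_prev) and obj_prev - obj <= tol * max(obj, 1.0):
            obj_prev = obj
            break
        obj_prev = obj
    if any(S[k] <= 0 for k in free_axes):
        raise NonPositiveScale(f"fitted scales {tuple(S)} not all positive")
    if fixed_z:
        S[2] = 0.5 * (S[0] + S[1])
    t = q_bar - R @ (S * p_bar)
    return RigidScaledTransform.from_parts(R, S, t)


# ---------------------------------------------------------------------------
# results object
# ---------------------------------------------------------------------------

@dataclass
class CalibrationResults:
    """Fitted calibration plus diagnostics.

    Attributes
    ----------
    transform : RigidScaledTransform
        Image-pixel to tracker map; 3x3 block = rotation x diag(spacings).
    tre_mm : float
        Final RMS point-to-line residual (mm).
    n_pairs, n_iterations : int
    converged : bool
    tre_history : list of float
        TRE after each outer iteration of the accepted restart.
    """

    transform: RigidScaledTransform
    tre_mm: float
    n_pairs: int
    n_iterations: int
    converged: bool
    tre_history: List[float]

    @property
    def pixel_spacings(self) -> Tuple[float, float]:
        """(lateral, axial) mm-per-pixel extracted from the transform."""
        return extract_pixel_spacings(self.transform)

    def compare_to(self, reference: RigidScaledTransform) -> dict:
        """Rotation (deg), translation (mm) and per-axis scale (%) errors."""
        R_err = self.transform.rotation @ reference.rotation.T
        dt = self.transform.translation - reference.translation
        s_est, s_ref = self.transform.scales, reference.scales
        return {
            "rotation_error_deg": rotation_angle_deg(R_err),
            "translation_error_mm": float(np.linalg.norm(dt)),
            "scale_error_pct_lateral": float(100 * abs(s_est[0] - s_ref[0]) / s_ref[0]),
            "scale_error_pct_axial": float(100 * abs(s_est[1] - s_ref[1]) / s_ref[1]),
        }

    def summary(self) -> str:
        lat, axi = self.pixel_spacings
        lines = [
            "Point-to-line probe calibration",
            "================================",
            f"pairs                 {self.n_pairs}",
            f"iterations            {self.n_iterations}",
            f"converged             {self.converged}",
            f"TRE (RMS, mm)         {self.tre_mm:.6g}",
            f"lateral spacing mm/px {lat:.6g}",
            f"axial spacing mm/px   {axi:.6g}",
            "transform (pixel -> tracker):",
            np.array2string(self.transform.matrix, precision=6, suppress_small=True),
        ]
        return "\n".join(lines)

    def plot_convergence(self, ax=None):
        """TRE against outer-iteration index."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(np.arange(1, len(self.tre_history) + 1), self.tre_history)
        ax.set_xlabel("iteration")
        ax.set_ylabel("TRE (mm)")
        ax.set_yscale("log")
        return ax


# ---------------------------------------------------------------------------
# outer ICP model
# ---------------------------------------------------------------------------

class PointLineCalibration:
    """Model object for the point-to-line calibration fit.

    Parameters
    ----------
    pairs
        Point-line observations; at least :data:`MIN_PAIRS`, with needle
        directions not all parallel.
    """

    def __init__(self, pairs: Sequence[PointLinePair]):
        pairs = list(pairs)
        if len(pairs) < MIN_PAIRS:
            raise InsufficientPairs(
                f"{len(pairs)} pairs given; need at least {MIN_PAIRS}"
            )
        dirs = np.array([p.line.direction for p in pairs])
        cos = np.abs(dirs @ dirs[0])
        if np.all(cos > np.cos(np.radians(_PARALLEL_LINES_DEG))):
            raise DegenerateLines(
                "all needle directions within 1 deg of parallel: "
                "calibration unidentifiable"
            )
        self.pairs = pairs
        self.points = np.array([[p.point.u, p.point.v, 0.0] for p in pairs])
        self.lines = [p.line for p in pairs]
        self._tips = np.array([l.tip for l in self.lines])
        self._dirs = np.array([l.direction for l in self.lines])

    @classmethod
    def from_observations(cls, points, lines) -> "PointLineCalibration":
        """Build from parallel sequences of (u, v) points and needle lines."""
        return cls(
            [
                PointLinePair(PixelPoint(float(p[0]), float(p[1])), l)
                for p, l in zip(points, lines)
            ]
        )

    # -- initialisation ---------------------------------------------------
    def _initial_transforms(self, nominal_spacing: float) -> List[RigidScaledTransform]:
        tips = np.array([l.tip for l in self.lines])
        c_tip = tips.mean(axis=0)
        c_target = np.mean(
            [closest_point_on_line(c_tip, l) for l in self.lines], axis=0
        )
        p_bar = self.points.mean(axis=0)
        S = np.full(3, nominal_spacing)
        inits = []
        for flip in (False, True):
            for quarter in range(4):
                a = quarter * np.pi / 2
                Rz = np.array(
                    [
                        [np.cos(a), -np.sin(a), 0.0],
                        [np.sin(a), np.cos(a), 0.0],
                        [0.0, 0.0, 1.0],
                    ]
                )
                R = Rz
                if flip:  # reverse the plane normal
                    R = Rz @ np.diag([1.0, -1.0, -1.0])
                t = c_target - R @ (S * p_bar)
                inits.append(RigidScaledTransform.from_parts(R, S, t))
        return inits

    # -- fitting ----------------------------------------------------------
    def fit(
        self,
        init: Optional[RigidScaledTransform] = None,
        tol: float = 1e-9,
        max_iter: int = 500,
        nominal_spacing: float = 0.1,
    ) -> CalibrationResults:
        """Run the ICP outer loop, multi-started unless ``init`` is given.

        Without an explicit ``init``, eight restarts are tried (quarter
        turns about the image-plane normal, with and without a normal
        flip, translation aligning the pixel centroid at the nominal
        isotropic spacing to the lines' mutual-closest-point centroid)
        and the lowest-TRE fit is kept.
        """
        candidates = [init] if init is not None else self._initial_transforms(
            nominal_spacing
        )
        best: Optional[CalibrationResults] = None
        for T0 in candidates:
            res = self._fit_single(T0, tol, max_iter)
            if best is None or res.tre_mm < best.tre_mm:
                best = res
        return best

    def _tre(self, T: RigidScaledTransform) -> float:
        mapped = self.points @ T.matrix[:3, :3].T + T.translation
        rel = mapped - self._tips
        perp = rel - (np.einsum("ij,ij->i", rel, self._dirs))[:, None] * self._dirs
        return float(np.sqrt(np.mean(np.einsum("ij,ij->i", perp, perp))))

    def _fit_single(
        self, T0: RigidScaledTransform, tol: float, max_iter: int
    ) -> CalibrationResults:
        T = T0
        tre = self._tre(T)
        history = [tre]
        converged = False
        iterations = 0
        for iterations in range(1, max_iter + 1):
            mapped = self.points @ T.matrix[:3, :3].T + T.translation
            rel = mapped - self._tips
            t_par = np.einsum("ij,ij->i", rel, self._dirs)
            targets = self._tips + t_par[:, None] * self._dirs
            T = solve_anisotropic_procrustes(
                self.points, targets, fixed_elevation_scale=True
            )
            tre_new = self._tre(T)
            history.append(tre_new)
            if abs(tre - tre_new) < tol:
                converged = True
                tre = tre_new
                break
            tre = tre_new
        return CalibrationResults(
            transform=T,
            tre_mm=tre,
            n_pairs=len(self.pairs),
            n_iterations=iterations,
            converged=converged,
            tre_history=history,
        )


def calibrate(
    pairs: Sequence[PointLinePair],
    init: Optional[RigidScaledTransform] = None,
    tol: float = 1e-9,
    max_iter: int = 500,
) -> CalibrationResults:
    """Functional wrapper: ``PointLineCalibration(pairs).fit(...)``."""
    return PointLineCalibration(pairs).fit(init=init, tol=tol, max_iter=max_iter)


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------

def compute_tre(T: RigidScaledTransform, pairs: Iterable[PointLinePair]) -> float:
    """RMS point-to-line distance (mm) of calibrated centroids."""
    pairs = list(pairs)
    if not pairs:
        raise EmptyPairs("TRE over an empty pair set")
    M, t = T.matrix[:3, :3], T.translation
    d2 = [
        point_to_line_distance(M @ [p.point.u, p.point.v, 0.0] + t, p.line) ** 2
        for p in pairs
    ]
    return float(np.sqrt(np.mean(d2)))


def extract_pixel_spacings(T: RigidScaledTransform) -> Tuple[float, float]:
    """(lateral, axial) mm-per-pixel from a calibration matrix.

    Column norms of the 3x3 block, cross-checked against its singular
    values (for rotation x diag the two coincide; disagreement means
    shear and raises NonDecomposable).
    """
    norms = require_rotation_times_diag(T.matrix[:3, :3])
    return float(norms[0]), float(norms[1])


def tre_vs_n_pairs(
    T_gt: RigidScaledTransform,
    config,
    rng=None,
    ns: Sequence[int] = (6, 9, 12, 15),
    n_trials: int = 50,
    n_holdout: int = 24,
    seed: int = 0,
) -> dict:
    """Held-out TRE as a function of the number of collected pairs.

    For each ``n`` and each trial: calibrate on ``n`` tracking-noisy
    observations, then evaluate the TRE of the *estimated* transform
    against held-out noiseless pairs (whose residual under the true
    calibration is zero).  Returns ``{n: mean TRE over trials}``.
    The workflow motivates collecting 12-15 pairs: the curve plateaus
    around a dozen measurements.
    """
    from .phantom import sample_calibration_observations

    if min(ns) < MIN_PAIRS:
        raise InsufficientPairs(f"smallest n must be >= {MIN_PAIRS}")
    if rng is None:
        rng = np.random.default_rng(seed)
    out = {n: [] for n in ns}
    n_max = max(ns)
    for trial in range(n_trials):
        obs = sample_calibration_observations(T_gt, n_max, config, rng)
        holdout = sample_calibration_observations(T_gt, n_holdout, config, rng)
        holdout_pairs = [PointLinePair(lab, pose) for lab, pose, _ in holdout]
        for n in ns:
            pairs = [PointLinePair(lab, noisy) for lab, _, noisy in obs[:n]]
            res = PointLineCalibration(pairs).fit()
            out[n].append(compute_tre(res.transform, holdout_pairs))
    return {n: float(np.mean(v)) for n, v in out.items()}
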