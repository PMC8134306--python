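"""Trajectory geometry and bending-label algebra.

An SEEG electrode is represented as an ordered sequence of 3D points in
world millimetres, nominally 1 mm apart (index 0 = entry, last index =
target).  Bending at an interior point ``x_i`` is described by either

* the *local displacement* ``lu``: the offset of the next point from a
  1 mm straight-ahead projection along the current direction
  ``v_hat = (x_i - x_{i-1}) / |x_i - x_{i-1}|``, i.e.
  ``x_{i+1} = x_i + 1 * v_hat + lu``; or
* the *bending direction* ``eb_hat``: the unit vector from ``x_i`` to
  ``x_{i+1}``, i.e. ``x_{i+1} = x_i + 1 * eb_hat``.

For 1 mm-spaced trajectories the two are equivalent:
``v_hat + lu = eb_hat``.  The *global displacement* ``gu`` is the
per-point offset of the implanted path from the index-matched rigid
(straight, bolt-direction) path.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import PchipInterpolator

__all__ = [
    "InvalidTrajectoryError",
    "Trajectory",
    "LabelSet",
    "AffineTransform",
    "interpolate_trajectory",
    "rigid_trajectory",
    "compute_labels",
    "advance_point",
    "apply_affine",
    "trajectory_mse",
    "unit",
]


class InvalidTrajectoryError(ValueError):
    """Raised for degenerate trajectory inputs (too few / coincident points)."""


def as_point(p) -> np.ndarray:
    """Coerce to a finite float64 (3,) array."""
    a = np.asarray(p, dtype=float).reshape(3)
    if not np.all(np.isfinite(a)):
        raise ValueError(f"point has non-finite components: {a}")
    return a


def unit(v) -> np.ndarray:
    """Normalize a 3-vector; raises on (near-)zero norm."""
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise ValueError("cannot normalize a zero-norm vector")
    return v / n


@dataclass
class Trajectory:
    """Ordered 3D points along an electrode path.

    Parameters
    ----------
    points : (N, 3) float array, world mm; index 0 is the entry,
        index N-1 the target.
    kind : one of ``rigid``, ``implanted``, ``predicted``.
    spacing_mm : nominal spacing between consecutive points.
    """

    points: np.ndarray
    kind: str = "rigid"
    spacing_mm: float = 1.0

    KINDS = ("rigid", "implanted", "predicted")

    def __post_init__(self):
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise InvalidTrajectoryError(
                f"points must be (N, 3), got {self.points.shape}"
            )
        if len(self.points) < 2:
            raise InvalidTrajectoryError("a trajectory needs at least 2 points")
        if not np.all(np.isfinite(self.points)):
            raise InvalidTrajectoryError("trajectory contains non-finite points")
        gaps = self.gaps()
        if np.any(gaps < 1e-9):
            raise InvalidTrajectoryError("consecutive trajectory points coincide")
        if self.kind not in self.KINDS:
            raise ValueError(f"kind must be one of {self.KINDS}, got {self.kind!r}")

    def __len__(self) -> int:
        return len(self.points)

    def gaps(self) -> np.ndarray:
        """Euclidean distance between consecutive points, mm."""
        return np.linalg.norm(np.diff(self.points, axis=0), axis=1)

    @property
    def entry(self) -> np.ndarray:
        return self.points[0]

    @property
    def target(self) -> np.ndarray:
        return self.points[-1]

    def length_mm(self) -> float:
        return float(self.gaps().sum())

    def directions(self) -> np.ndarray:
        """Unit step directions v_hat_i = (x_i - x_{i-1})/|.|, shape (N-1, 3)."""
        d = np.diff(self.points, axis=0)
        return d / np.linalg.norm(d, axis=1, keepdims=True)

    def replace(self, **kw) -> "Trajectory":
        return dataclasses.replace(self, **kw)


@dataclass
class LabelSet:
    """Per-interior-point bending labels for a trajectory of I points.

    Labels are defined for interior indices ``i = first_index .. I-2``
    (a predecessor and a successor point are both required), stored as
    (M, 3) arrays with ``M = I - 2`` and ``first_index = 1``.
    """

    v_hat: np.ndarray   # unit travel direction at x_i
    lu: np.ndarray      # local displacement, mm
    eb_hat: np.ndarray  # unit bending direction x_i -> x_{i+1}
    x_p: np.ndarray     # straight-ahead projected point x_i + spacing*v_hat
    gu: np.ndarray      # global displacement x_i - rigid_i, mm
    first_index: int = 1
    spacing_mm: float = 1.0

    def __len__(self) -> int:
        return len(self.lu)

    @property
    def indices(self) -> np.ndarray:
        return np.arange(self.first_index, self.first_index + len(self))


@dataclass
class AffineTransform:
    """4x4 homogeneous world-mm -> world-mm (or voxel -> world) map."""

    matrix: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (4, 4):
            raise ValueError("affine matrix must be 4x4")
        if not np.allclose(self.matrix[3], [0.0, 0.0, 0.0, 1.0], atol=1e-12):
            raise ValueError("bottom row of an affine must be (0, 0, 0, 1)")
        if abs(np.linalg.det(self.matrix[:3, :3])) < 1e-12:
            raise ValueError("affine matrix is singular")

    @classmethod
    def identity(cls) -> "AffineTransform":
        return cls(np.eye(4))

    @classmethod
    def from_translation(cls, t) -> "AffineTransform":
        m = np.eye(4)
        m[:3, 3] = np.asarray(t, dtype=float)
        return cls(m)

    @property
    def linear(self) -> np.ndarray:
        return self.matrix[:3, :3]

    @property
    def translation(self) -> np.ndarray:
        return self.matrix[:3, 3]

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map (N, 3) or (3,) world points homogeneously."""
        p = np.asarray(points, dtype=float)
        return p @ self.linear.T + self.translation

    def inverse(self) -> "AffineTransform":
        return AffineTransform(np.linalg.inv(self.matrix))

    def compose(self, other: "AffineTransform") -> "AffineTransform":
        """self ∘ other (apply ``other`` first)."""
        return AffineTransform(self.matrix @ other.matrix)


# ---------------------------------------------------------------------------
# construction


def _dedupe_controls(control_points) -> np.ndarray:
    pts = np.atleast_2d(np.asarray(control_points, dtype=float))
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise InvalidTrajectoryError("control points must be (N, 3)")
    keep = [0]
    for j in range(1, len(pts)):
        if np.linalg.norm(pts[j] - pts[keep[-1]]) > 1e-9:
            keep.append(j)
    return pts[keep]


def interpolate_trajectory(
    control_points,
    spacing: float = 1.0,
    kind: str = "implanted",
    n_dense: int = 16384,
) -> Trajectory:
    """Resample a shape-preserving cubic Hermite (PCHIP) curve at ~``spacing`` mm.

    The curve is parametrized by cumulative chord length over the control
    points and evaluated at uniform arc-length targets ``h = L / round(L /
    spacing)`` so the first and last samples coincide with the first and
    last control points and all gaps are mutually equal.  Arc length is
    tabulated on a dense grid and each parameter target is refined with a
    Newton correction using the analytic curve speed.

    Duplicate consecutive control points (e.g. coincident CT contact
    detections) are dropped before fitting.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    pts = _dedupe_controls(control_points)
    if len(pts) < 2:
        raise InvalidTrajectoryError(
            "need at least 2 distinct control points to interpolate"
        )
    chord = np.concatenate(
        [[0.0], np.cumsum(np.linalg.norm(np.diff(pts, axis=0), axis=1))]
    )
    curve = PchipInterpolator(chord, pts, axis=0)
    speed_fn = curve.derivative()

    t_dense = np.linspace(0.0, chord[-1], n_dense)
    xyz = curve(t_dense)
    seg = np.linalg.norm(np.diff(xyz, axis=0), axis=1)
    s_dense = np.concatenate([[0.0], np.cumsum(seg)])
    total = s_dense[-1]

    n_gaps = max(1, int(round(total / spacing)))
    s_targets = np.linspace(0.0, total, n_gaps + 1)
    t = np.interp(s_targets, s_dense, t_dense)
    # Newton refinement: ds/dt = |curve'(t)|
    for _ in range(3):
        s_at_t = np.interp(t, t_dense, s_dense)
        sp = np.linalg.norm(speed_fn(t), axis=1)
        sp = np.where(sp < 1e-12, 1.0, sp)
        t = np.clip(t - (s_at_t - s_targets) / sp, 0.0, chord[-1])
    out = curve(t)
    out[0] = pts[0]
    out[-1] = pts[-1]
    return Trajectory(out, kind=kind, spacing_mm=spacing)


def rigid_trajectory(
    entry, bolt_direction, depth: float, spacing: float = 1.0
) -> Trajectory:
    """Straight 1 mm-spaced trajectory along the bolt axis.

    Points are ``entry + k * spacing * b_hat`` for ``k = 0 ..
    floor(depth / spacing)``.
    """
    entry = as_point(entry)
    b_hat = unit(bolt_direction)
    if depth <= 0:
        raise ValueError("depth must be positive")
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    n_steps = int(np.floor(depth / spacing + 1e-9))
    if n_steps < 1:
        raise InvalidTrajectoryError("depth shorter than one spacing step")
    k = np.arange(n_steps + 1)[:, None]
    return Trajectory(entry + k * spacing * b_hat, kind="rigid", spacing_mm=spacing)


# ---------------------------------------------------------------------------
# label algebra


def compute_labels(
    implanted: Trajectory, rigid: Trajectory | None = None
) -> LabelSet:
    """Bending labels lu / eb_hat (and gu vs. the rigid path) per interior point.

    For each interior index ``1 <= i <= I-2``::

        v_hat_i = (x_i - x_{i-1}) / |x_i - x_{i-1}|
        x_p     = x_i + spacing * v_hat_i
        lu_i    = x_{i+1} - x_p
        eb_i    = (x_{i+1} - x_i) / |x_{i+1} - x_i|
        gu_i    = x_i - r_i            (index-matched rigid point)

    ``rigid`` defaults to the implanted trajectory itself (gu = 0).
    """
    x = implanted.points
    if len(x) < 3:
        raise InvalidTrajectoryError("need at least 3 points to compute labels")
    d = np.diff(x, axis=0)
    norms = np.linalg.norm(d, axis=1)
    if np.any(norms < 1e-12):
        raise InvalidTrajectoryError("coincident consecutive points")
    dirs = d / norms[:, None]
    spacing = implanted.spacing_mm

    v_hat = dirs[:-1]                      # v_hat_i for i = 1..I-2
    eb_hat = dirs[1:]                      # direction x_i -> x_{i+1}
    x_p = x[1:-1] + spacing * v_hat
    lu = x[2:] - x_p

    if rigid is None:
        gu = np.zeros_like(lu)
    else:
        r = rigid.points
        if len(r) < len(x) - 1:
            raise InvalidTrajectoryError(
                f"rigid trajectory too short for index matching "
                f"({len(r)} < {len(x) - 1})"
            )
        gu = x[1:-1] - r[1 : len(x) - 1]

    return LabelSet(
        v_hat=v_hat, lu=lu, eb_hat=eb_hat, x_p=x_p, gu=gu,
        first_index=1, spacing_mm=spacing,
    )


def advance_point(
    x_i, v_hat, label, label_kind: str = "lu", spacing: float = 1.0
) -> np.ndarray:
    """Advance the electrode tip one step from ``x_i``.

    ``lu`` mode: ``x_i + spacing * v_hat + label``.  ``eb`` mode:
    ``x_i + spacing * unit(label)`` — a regressed bending direction is
    renormalized to unit length before stepping, since a network output
    is not constrained to unit norm.
    """
    x_i = as_point(x_i)
    label = np.asarray(label, dtype=float).reshape(3)
    if not np.all(np.isfinite(label)):
        raise ValueError("label has non-finite components")
    if label_kind == "lu":
        v = np.asarray(v_hat, dtype=float).reshape(3)
        if abs(np.linalg.norm(v) - 1.0) > 1e-6:
            raise ValueError("v_hat must be unit-norm in lu mode")
        return x_i + spacing * v + label
    if label_kind == "eb":
        if np.linalg.norm(label) < 1e-12:
            raise ValueError("zero-norm eb label")
        return x_i + spacing * unit(label)
    raise ValueError(f"label_kind must be 'lu' or 'eb', got {label_kind!r}")


def apply_affine(traj: Trajectory, transform: AffineTransform) -> Trajectory:
    """Map every trajectory point through a homogeneous affine."""
    return traj.replace(points=transform.apply(traj.points))


def trajectory_mse(predicted: Trajectory, implanted: Trajectory) -> float:
    """MSE_i: mean squared Euclidean distance between index-matched points, mm^2."""
    if len(predicted) != len(implanted):
        raise InvalidTrajectoryError(
            f"trajectory length mismatch: {len(predicted)} vs {len(implanted)}"
        )
    d = predicted.points - implanted.points
    return float(np.mean(np.sum(d * d, axis=1)))
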