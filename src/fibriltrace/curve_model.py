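"""Parametric space curves for fibril centerlines.

A fibril centerline is modeled in a local right-handed frame as a helix about
the local z axis plus a polynomial deviation::

    C(t) = ( a*cos(w*t + phi) + sum_i c_i t^i,
             a*sin(w*t + phi) + sum_i d_i t^i,
             t )                                  for t in [t0, t1]  (nm)

and mapped into the volume frame by a rigid pose (rotation + translation).
With ``a = 0`` and all polynomial coefficients zero the curve degenerates to a
straight segment along the local axis.  The parameter ``t`` is the local axial
coordinate, not arclength; arclength is obtained by quadrature.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial import cKDTree


@dataclass(frozen=True)
class SpaceCurve:
    """Helix-plus-polynomial space curve in a rigid pose.

    Parameters
    ----------
    rotation : (3, 3) proper rotation, local frame -> volume frame.
    translation : (3,) nm offset of the local origin in the volume frame.
    helix_radius_nm : helix amplitude ``a`` (>= 0).
    helix_pitch_rad_per_nm : angular rate ``w`` of the helix.
    helix_phase_rad : phase ``phi``.
    poly_x, poly_y : polynomial coefficients (c0, c1, ...) in increasing order.
    t_range : closed interval [t0, t1] in nm along the local axis, t1 > t0.
    """

    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))
    helix_radius_nm: float = 0.0
    helix_pitch_rad_per_nm: float = 0.0
    helix_phase_rad: float = 0.0
    poly_x: tuple = (0.0,)
    poly_y: tuple = (0.0,)
    t_range: tuple = (0.0, 1.0)

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float)
        tr = np.asarray(self.translation, dtype=float)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", tr)
        object.__setattr__(self, "poly_x", tuple(float(c) for c in self.poly_x))
        object.__setattr__(self, "poly_y", tuple(float(c) for c in self.poly_y))
        t0, t1 = self.t_range
        if not t1 > t0:
            raise ValueError(f"t_range must satisfy t1 > t0, got {self.t_range}")
        if self.helix_radius_nm < 0:
            raise ValueError("helix_radius_nm must be >= 0")
        if R.shape != (3, 3) or not np.allclose(R @ R.T, np.eye(3), atol=1e-8):
            raise ValueError("rotation must be a 3x3 orthonormal matrix")
        if np.linalg.det(R) < 0:
            raise ValueError("rotation must be proper (det +1)")

    # -- local-frame pieces -------------------------------------------------
    def _local(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        a, w, phi = self.helix_radius_nm, self.helix_pitch_rad_per_nm, self.helix_phase_rad
        x = a * np.cos(w * t + phi) + np.polynomial.polynomial.polyval(t, self.poly_x)
        y = a * np.sin(w * t + phi) + np.polynomial.polynomial.polyval(t, self.poly_y)
        return np.stack([x, y, t], axis=-1)

    def _local_deriv(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        a, w, phi = self.helix_radius_nm, self.helix_pitch_rad_per_nm, self.helix_phase_rad
        dcx = np.polynomial.polynomial.polyder(self.poly_x) if len(self.poly_x) > 1 else [0.0]
        dcy = np.polynomial.polynomial.polyder(self.poly_y) if len(self.poly_y) > 1 else [0.0]
        dx = -a * w * np.sin(w * t + phi) + np.polynomial.polynomial.polyval(t, dcx)
        dy = a * w * np.cos(w * t + phi) + np.polynomial.polynomial.polyval(t, dcy)
        return np.stack([dx, dy, np.ones_like(t)], axis=-1)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "SpaceCurve":
        """Compose an extra rigid motion (applied in the volume frame)."""
        R = np.asarray(rotation, dtype=float)
        tr = np.asarray(translation, dtype=float)
        return replace(self, rotation=R @ self.rotation,
                       translation=R @ self.translation + tr)


def evaluate(curve: SpaceCurve, t_values) -> np.ndarray:
    """Points on the curve in the volume frame (nm), shape (n, 3).

    Values outside ``t_range`` are clamped to the interval ends.
    """
    t = np.clip(np.asarray(t_values, dtype=float), *curve.t_range)
    pts = curve._local(t)
    return pts @ curve.rotation.T + curve.translation


def tangent(curve: SpaceCurve, t) -> np.ndarray:
    """Unit tangent(s) at t, in the volume frame.  Scalar t -> shape (3,)."""
    scalar = np.isscalar(t)
    tt = np.clip(np.atleast_1d(np.asarray(t, dtype=float)), *curve.t_range)
    d = curve._local_deriv(tt) @ curve.rotation.T
    d /= np.linalg.norm(d, axis=-1, keepdims=True)
    return d[0] if scalar else d


def mean_tangent(curve: SpaceCurve, n: int = 33) -> np.ndarray:
    """Average of unit tangents at n evenly spaced nodes, renormalized."""
    t = np.linspace(*curve.t_range, n)
    m = tangent(curve, t).mean(axis=0)
    return m / np.linalg.norm(m)


def curve_length(curve: SpaceCurve, rtol: float = 1e-4) -> float:
    """Arclength by adaptive trapezoid quadrature of ||C'(t)||.

    Doubles the node count until successive estimates agree to ``rtol``.
    Exact (to float) for straight segments.
    """
    t0, t1 = curve.t_range

    def estimate(n):
        t = np.linspace(t0, t1, n)
        speed = np.linalg.norm(curve._local_deriv(t), axis=-1)
        return np.trapezoid(speed, t)

    n = 65
    prev = estimate(n)
    for _ in range(12):
        n = 2 * n - 1
        cur = estimate(n)
        if abs(cur - prev) <= rtol * max(abs(cur), 1e-12):
            return float(cur)
        prev = cur
    return float(cur)


def sample_points(curve: SpaceCurve, sampling_nm: float) -> np.ndarray:
    """Points at roughly ``sampling_nm`` arc spacing along the curve."""
    if sampling_nm <= 0:
        raise ValueError("sampling_nm must be positive")
    length = curve_length(curve)
    n = max(2, int(np.ceil(length / sampling_nm)) + 1)
    t = np.linspace(*curve.t_range, n)
    return evaluate(curve, t)


def min_distance_between(c1: SpaceCurve, c2: SpaceCurve,
                         sampling_nm: float = 0.5) -> dict:
    """Distance summary between two curves.

    For each sample on ``c1`` the distance to the nearest sample on ``c2``
    (and vice versa).  Returns ``min`` (global minimum over both directions),
    ``mean_of_min`` (symmetric mean of the two directional means — the pair
    distance used by nearest-neighbor statistics) and the two per-sample
    profiles.
    """
    p1 = sample_points(c1, sampling_nm)
    p2 = sample_points(c2, sampling_nm)
    if len(p1) == 0 or len(p2) == 0:
        raise ValueError("degenerate sampling: empty point set")
    d12 = cKDTree(p2).query(p1)[0]
    d21 = cKDTree(p1).query(p2)[0]
    return {
        "min": float(min(d12.min(), d21.min())),
        "mean_of_min": float(0.5 * (d12.mean() + d21.mean())),
        "profile_12": d12,
        "profile_21": d21,
    }


def pair_distance(c1: SpaceCurve, c2: SpaceCurve, sampling_nm: float = 0.5) -> float:
    """Symmetric mean-of-minima pair distance (nm)."""
    return min_distance_between(c1, c2, sampling_nm)["mean_of_min"]


def rotation_about_axis(axis, angle_rad: float) -> np.ndarray:
    """Proper rotation matrix about an arbitrary axis (Rodrigues)."""
    u = np.asarray(axis, dtype=float)
    u = u / np.linalg.norm(u)
    K = np.array([[0, -u[2], u[1]], [u[2], 0, -u[0]], [-u[1], u[0], 0]])
    return np.eye(3) + np.sin(angle_rad) * K + (1 - np.cos(angle_rad)) * (K @ K)


def frame_from_axis(direction) -> np.ndarray:
    """Rotation whose third column is ``direction`` (local z -> direction)."""
    z = np.asarray(direction, dtype=float)
    z = z / np.linalg.norm(z)
    helper = np.array([1.0, 0.0, 0.0])
    if abs(z @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    x = np.cross(helper, z)
    x /= np.linalg.norm(x)
    y = np.cross(z, x)
    return np.column_stack([x, y, z])


def recenter_parameter(curve: SpaceCurve) -> SpaceCurve:
    """Equivalent curve with t_range symmetric about 0.

    Shifts the parameter origin to the interval midpoint (absorbing the shift
    into the pose, the helix phase and a polynomial re-expansion), so that
    slope-like coefficients pivot about the curve's middle.  The point set is
    unchanged.
    """
    t0, t1 = curve.t_range
    tm = 0.5 * (t0 + t1)
    if tm == 0.0:
        return curve
    P = np.polynomial.Polynomial
    shift = P([tm, 1.0])
    new_px = tuple(P(curve.poly_x)(shift).coef)
    new_py = tuple(P(curve.poly_y)(shift).coef)
    return replace(
        curve,
        translation=curve.translation + curve.rotation @ np.array([0.0, 0.0, tm]),
        helix_phase_rad=curve.helix_phase_rad + curve.helix_pitch_rad_per_nm * tm,
        poly_x=new_px, poly_y=new_py,
        t_range=(t0 - tm, t1 - tm))


def curve_to_dict(curve: SpaceCurve) -> dict:
    """JSON-ready representation of a curve."""
    return {
        "rotation": curve.rotation.tolist(),
        "translation": curve.translation.tolist(),
        "helix_radius_nm": curve.helix_radius_nm,
        "helix_pitch_rad_per_nm": curve.helix_pitch_rad_per_nm,
        "helix_phase_rad": curve.helix_phase_rad,
        "poly_x": list(curve.poly_x),
        "poly_y": list(curve.poly_y),
        "t_range": list(curve.t_range),
    }


def curve_from_dict(d: dict) -> SpaceCurve:
    return SpaceCurve(rotation=np.asarray(d["rotation"], dtype=float),
                      translation=np.asarray(d["translation"], dtype=float),
                      helix_radius_nm=d["helix_radius_nm"],
                      helix_pitch_rad_per_nm=d["helix_pitch_rad_per_nm"],
                      helix_phase_rad=d["helix_phase_rad"],
                      poly_x=tuple(d["poly_x"]), poly_y=tuple(d["poly_y"]),
                      t_range=tuple(d["t_range"]))


def line_curve(point, direction, t_range) -> SpaceCurve:
    """Straight segment through ``point`` along ``direction`` over t_range."""
    R = frame_from_axis(direction)
    return SpaceCurve(rotation=R, translation=np.asarray(point, dtype=float),
                      t_range=tuple(t_range))
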