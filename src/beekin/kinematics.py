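"""Rigid-body orientation from three markers, Euler angles, smoothing and
body-frame angular velocity.

Conventions (used everywhere in the package):

* body axes: x forward (toward the front marker), y to the animal's left
  (right marker → left marker), z = x × y up for a level animal —
  a right-handed frame;
* Euler composition: body→world ``R = Rz(yaw) @ Ry(pitch) @ Rx(roll)``
  (yaw-pitch-roll convention), pitch in [-π/2, π/2];
* angular velocity is taken from the full rotation sequence,
  Ω = unskew(Rᵀ dR/dt) expressed in the body frame, so it stays correct
  under nonzero pitch/roll; it coincides with d(yaw)/dt when pitch=roll=0.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.interpolate import CubicSpline, make_smoothing_spline
from scipy.linalg import solveh_banded

from .series import MarkerFrameSeries, PoseSeries, RotationFrameSeries, VelocitySeries

__all__ = [
    "SmoothingConfig",
    "DegenerateGeometryError",
    "body_frame_from_markers",
    "frames_from_markers",
    "rotation_to_ypr",
    "ypr_to_rotation",
    "pose_from_markers",
    "smooth_pose",
    "angular_velocity_z",
    "resample_roundtrip",
    "flatten_to_topview",
]


class DegenerateGeometryError(ValueError):
    """Raised when the three markers of a frame are collinear or coincident."""


@dataclass
class SmoothingConfig:
    """Smoothing-spline strength expressed as effective degrees of freedom.

    ``lambda_df`` is the trace of the smoother (hat) matrix of the penalized
    cubic spline: n means interpolation, 2 a straight line. Default 150,
    appropriate for ~10 s flights sampled at 500 fps.
    """

    lambda_df: float = 150.0


_COLLINEAR_TOL = 1e-12


def body_frame_from_markers(left, right, front):
    """Body frame from one frame's three markers.

    Returns ``(origin, R)`` with origin the marker centroid and R the
    body→world rotation whose columns are the body x/y/z axes.
    """
    o, R = _frames_vectorized(
        np.asarray(left, float)[None], np.asarray(right, float)[None],
        np.asarray(front, float)[None])
    return o[0], R[0]


def _frames_vectorized(left, right, front):
    origin = (left + right + front) / 3.0
    y = left - right
    ny = np.linalg.norm(y, axis=-1, keepdims=True)
    f = front - origin
    # degenerate if left==right or front on the left-right line
    cross = np.cross(y, f)
    bad = (ny[..., 0] < _COLLINEAR_TOL) | (
        np.linalg.norm(cross, axis=-1) < _COLLINEAR_TOL * np.maximum(ny[..., 0], 1.0))
    if np.any(bad):
        idx = int(np.flatnonzero(bad)[0])
        raise DegenerateGeometryError(
            f"collinear or coincident markers at frame {idx}")
    y = y / ny
    x = f - np.sum(f * y, axis=-1, keepdims=True) * y
    x = x / np.linalg.norm(x, axis=-1, keepdims=True)
    z = np.cross(x, y)
    R = np.stack([x, y, z], axis=-1)  # columns are the body axes
    return origin, R


def frames_from_markers(series: MarkerFrameSeries) -> RotationFrameSeries:
    """Vectorized :func:`body_frame_from_markers` over a whole series."""
    origin, R = _frames_vectorized(series.left, series.right, series.front)
    return RotationFrameSeries(times=series.times, origin=origin, R=R)


_GIMBAL_TOL = 1e-8


def rotation_to_ypr(R: np.ndarray):
    """Decompose a proper rotation into (yaw, pitch, roll), radians.

    Inverse of ``Rz(yaw)@Ry(pitch)@Rx(roll)``; pitch ∈ [-π/2, π/2]. At gimbal
    lock (|pitch| = π/2) roll is set to 0, yaw absorbs the remaining rotation,
    and a warning is emitted.
    """
    R = np.asarray(R, dtype=float)
    single = R.ndim == 2
    if single:
        R = R[None]
    sp = np.clip(-R[:, 2, 0], -1.0, 1.0)
    pitch = np.arcsin(sp)
    locked = np.abs(np.abs(sp) - 1.0) < _GIMBAL_TOL
    yaw = np.arctan2(R[:, 1, 0], R[:, 0, 0])
    roll = np.arctan2(R[:, 2, 1], R[:, 2, 2])
    if np.any(locked):
        warnings.warn(
            "gimbal lock (|pitch| = pi/2): roll set to 0, yaw absorbs the sum",
            RuntimeWarning, stacklevel=2)
        # at sp = ±1: R[0,1] = -cos(yaw ∓ roll)·..., use the stable block
        yaw_l = np.arctan2(-R[:, 0, 1], R[:, 1, 1])
        yaw = np.where(locked, yaw_l, yaw)
        roll = np.where(locked, 0.0, roll)
        pitch = np.where(locked, np.sign(sp) * np.pi / 2, pitch)
    if single:
        return float(yaw[0]), float(pitch[0]), float(roll[0])
    return yaw, pitch, roll


def ypr_to_rotation(yaw, pitch, roll) -> np.ndarray:
    """Compose body→world ``R = Rz(yaw) @ Ry(pitch) @ Rx(roll)`` (vectorized)."""
    yaw, pitch, roll = np.broadcast_arrays(
        np.asarray(yaw, float), np.asarray(pitch, float), np.asarray(roll, float))
    cy, sy = np.cos(yaw), np.sin(yaw)
    cp, sp = np.cos(pitch), np.sin(pitch)
    cr, sr = np.cos(roll), np.sin(roll)
    R = np.empty(yaw.shape + (3, 3))
    R[..., 0, 0] = cy * cp
    R[..., 0, 1] = cy * sp * sr - sy * cr
    R[..., 0, 2] = cy * sp * cr + sy * sr
    R[..., 1, 0] = sy * cp
    R[..., 1, 1] = sy * sp * sr + cy * cr
    R[..., 1, 2] = sy * sp * cr - cy * sr
    R[..., 2, 0] = -sp
    R[..., 2, 1] = cp * sr
    R[..., 2, 2] = cp * cr
    return R


def pose_from_markers(series: MarkerFrameSeries) -> PoseSeries:
    """Markers → unwrapped yaw/pitch/roll pose for a whole series."""
    frames = frames_from_markers(series)
    yaw, pitch, roll = rotation_to_ypr(frames.R)
    return PoseSeries(times=series.times, fps=series.fps, part=series.part,
                      yaw=np.unwrap(yaw), pitch=pitch, roll=roll)


# ---------------------------------------------------------------------------
# smoothing spline with an effective-degrees-of-freedom parameterization

def _edf_matrices(x: np.ndarray):
    """Banded pieces of the natural-spline penalty for the Reinsch form.

    Returns (R, QtQ, Qt) with R the (n-2) tridiagonal Gram matrix of the
    second-derivative basis and Q the n×(n-2) second-difference operator, so
    that the penalized fit is g = y - lam*Q @ solve(R + lam*QᵀQ, Qᵀy) and the
    hat-matrix trace is n - lam*tr((R + lam*QᵀQ)⁻¹ QᵀQ).
    """
    h = np.diff(x)
    n = x.size
    m = n - 2
    # Q columns j: entries 1/h[j], -(1/h[j]+1/h[j+1]), 1/h[j+1] at rows j..j+2
    a = 1.0 / h[:-1]
    c = 1.0 / h[1:]
    b = -(a + c)
    # R tridiagonal
    R_diag = (h[:-1] + h[1:]) / 3.0
    R_off = h[1:-1] / 6.0
    # QtQ pentadiagonal: (QᵀQ)_{jk} = Σ_i Q_ij Q_ik
    d0 = a * a + b * b + c * c
    d1 = b[:-1] * a[1:] + c[:-1] * b[1:]
    d2 = c[:-2] * a[2:]
    return (R_diag, R_off), (d0, d1, d2), (a, b, c), m


def _banded_upper(m, d0, d1, d2):
    ab = np.zeros((3, m))
    ab[2] = d0
    ab[1, 1:] = d1
    ab[0, 2:] = d2
    return ab


def effective_df(x: np.ndarray, lam: float) -> float:
    """Trace of the smoothing-spline hat matrix for penalty ``lam``.

    Uses the Reinsch banded form; O(n²) via chunked banded solves.
    """
    (Rd, Ro), (q0, q1, q2), _, m = _edf_matrices(x)
    n = x.size
    if lam == 0.0:
        return float(n)
    # M = R + lam*QtQ, symmetric pentadiagonal, upper banded storage
    ab = _banded_upper(m, Rd + lam * q0, (Ro + lam * q1), lam * q2)
    # tr(M^{-1} QtQ) = sum_j (M^{-1} b_j)_j with b_j columns of QtQ,
    # built in column chunks to keep memory O(m * chunk)
    tr = 0.0
    step = 512
    for j0 in range(0, m, step):
        j1 = min(j0 + step, m)
        cols = np.zeros((m, j1 - j0))
        j = np.arange(j0, j1)
        local = j - j0
        cols[j, local] = q0[j]
        for off, band in ((1, q1), (2, q2)):
            ok = j - off >= 0
            cols[j[ok] - off, local[ok]] = band[j[ok] - off]
            ok = j + off < m
            cols[j[ok] + off, local[ok]] = band[j[ok]]
        X = solveh_banded(ab, cols)
        tr += float(X[j, local].sum())
    return float(n - lam * tr)


def penalty_for_df(x: np.ndarray, df: float, rtol: float = 1e-6) -> float:
    """Invert ``effective_df``: the penalty whose smoother has ``df`` d.o.f.

    Bisection on log(lam); edf is strictly decreasing in lam from n to 2.
    """
    n = x.size
    if not 2.0 <= df <= n:
        raise ValueError(f"lambda_df must lie in [2, n={n}], got {df}")
    if df >= n - 1e-9:
        return 0.0
    lo, hi = 1e-16, 1e-12
    while effective_df(x, hi) > df:
        lo, hi = hi, hi * 100.0
        if hi > 1e18:
            break
    for _ in range(80):
        mid = np.sqrt(lo * hi)
        if effective_df(x, mid) > df:
            lo = mid
        else:
            hi = mid
        if hi / lo < 1 + rtol:
            break
    return float(np.sqrt(lo * hi))


def smooth_pose(series: PoseSeries, cfg: SmoothingConfig | None = None) -> PoseSeries:
    """Penalized cubic smoothing spline on each angle channel.

    The penalty is solved so that the smoother's effective degrees of freedom
    equals ``cfg.lambda_df``; yaw is smoothed on its unwrapped values. The
    spline is evaluated back on the original time grid.
    """
    cfg = cfg or SmoothingConfig()
    n = len(series)
    if n < 4:
        raise ValueError("smooth_pose needs at least 4 samples")
    if not 2.0 <= cfg.lambda_df <= n:
        raise ValueError(f"lambda_df must lie in [2, {n}], got {cfg.lambda_df}")
    lam = penalty_for_df(series.times, cfg.lambda_df)
    out = {}
    for name in ("yaw", "pitch", "roll"):
        y = getattr(series, name)
        if lam == 0.0:
            out[name] = y.copy()
        else:
            spl = make_smoothing_spline(series.times, y, lam=lam)
            out[name] = spl(series.times)
    return series.with_angles(**out)


# ---------------------------------------------------------------------------

_RAD2DEG = 180.0 / np.pi


def angular_velocity_z(series: PoseSeries) -> VelocitySeries:
    """Body-frame angular velocity about z, deg/s.

    Rebuilds R(t) per frame and takes Ω(t) = unskew(Rᵀ dR/dt) with dR/dt by
    central differences (one-sided at the endpoints).
    """
    n = len(series)
    if n < 3:
        raise ValueError("angular_velocity_z needs at least 3 samples")
    R = ypr_to_rotation(series.yaw, series.pitch, series.roll)
    dR = np.empty_like(R)
    dt = 1.0 / series.fps
    dR[1:-1] = (R[2:] - R[:-2]) / (2 * dt)
    dR[0] = (R[1] - R[0]) / dt
    dR[-1] = (R[-1] - R[-2]) / dt
    # body-frame skew matrix Ω× = Rᵀ dR/dt; ω_z = (Ω×)[1,0] (antisymmetrized)
    W = np.einsum("nji,njk->nik", R, dR)
    omega_z = 0.5 * (W[:, 1, 0] - W[:, 0, 1])
    return VelocitySeries(times=series.times, fps=series.fps, part=series.part,
                          omega_z=omega_z * _RAD2DEG)


def resample_roundtrip(series: PoseSeries, target_fps: float) -> PoseSeries:
    """Emulate a low-frame-rate recording: decimate, then spline back up.

    Decimates by the integer stride nearest fps/target_fps and re-interpolates
    each (unwrapped) angle channel onto the original time grid with an
    interpolating cubic spline; the output keeps the original length and fps.
    """
    if not 0 < target_fps <= series.fps:
        raise ValueError(f"target_fps must lie in (0, fps], got {target_fps}")
    stride = max(1, int(round(series.fps / target_fps)))
    if stride == 1:
        return replace(series)
    t_low = series.times[::stride]
    out = {}
    for name in ("yaw", "pitch", "roll"):
        y = getattr(series, name)[::stride]
        spl = CubicSpline(t_low, y)
        out[name] = spl(series.times)
    return series.with_angles(**out)


def flatten_to_topview(series: MarkerFrameSeries) -> MarkerFrameSeries:
    """Emulate a single top-view camera: per frame, replace all marker z
    coordinates by their mean, so the downstream pose has pitch = roll = 0."""
    zbar = (series.left[:, 2] + series.right[:, 2] + series.front[:, 2]) / 3.0
    def flat(a):
        b = a.copy()
        b[:, 2] = zbar
        return b
    return MarkerFrameSeries(times=series.times, fps=series.fps, part=series.part,
                             left=flat(series.left), right=flat(series.right),
                             front=flat(series.front))
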