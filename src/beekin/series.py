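"""Time-series containers shared by all stages.

Angles are radians internally and degrees in files; angular velocities are
deg/s everywhere (the field's customary unit for insect saccades); times are
seconds on a uniform grid; marker positions are meters.
"""
from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal

import numpy as np

Part = Literal["head", "thorax"]

_TIME_RTOL = 1e-9


def _check_uniform_times(times: np.ndarray, fps: float) -> None:
    if times.ndim != 1:
        raise ValueError("times must be a 1-D array")
    if times.size < 2:  # empty / single-frame series are trivially uniform
        return
    if np.any(~np.isfinite(times)):
        raise ValueError("times contain non-finite values")
    dt = np.diff(times)
    if np.any(dt <= 0):
        raise ValueError("times must be strictly increasing")
    if np.max(np.abs(dt - 1.0 / fps)) > max(_TIME_RTOL, 1e-6 / fps):
        raise ValueError("times are not uniformly spaced at 1/fps")


def time_grid(n: int, fps: float, t0: float = 0.0) -> np.ndarray:
    """Uniform time grid of ``n`` samples at ``fps`` frames/s."""
    return t0 + np.arange(n) / fps


@dataclass
class MarkerFrameSeries:
    """Per-frame 3-D positions of the left/right/front markers of one body part.

    The three markers form a rigid (nominally equilateral) triangle glued to
    the head or thorax; they must never be collinear within a frame.
    """

    times: np.ndarray
    fps: float
    part: Part
    left: np.ndarray    # (n, 3) meters
    right: np.ndarray   # (n, 3)
    front: np.ndarray   # (n, 3)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        for name in ("left", "right", "front"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (self.times.size, 3):
                raise ValueError(f"{name} must have shape (n, 3)")
            if np.any(~np.isfinite(arr)):
                raise ValueError(f"{name} contains non-finite positions")
            setattr(self, name, arr)
        _check_uniform_times(self.times, self.fps)

    def __len__(self) -> int:
        return self.times.size


@dataclass
class RotationFrameSeries:
    """Per-frame rigid-body frame: centroid origin and body→world rotation."""

    times: np.ndarray
    origin: np.ndarray  # (n, 3)
    R: np.ndarray       # (n, 3, 3), proper rotations

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)
        self.R = np.asarray(self.R, dtype=float)
        n = self.times.size
        if self.origin.shape != (n, 3) or self.R.shape != (n, 3, 3):
            raise ValueError("origin must be (n,3) and R (n,3,3)")

    def validate(self, atol: float = 1e-9) -> None:
        eye = np.eye(3)
        err = np.max(np.abs(np.einsum("nij,nik->njk", self.R, self.R) - eye))
        if err > atol:
            raise ValueError(f"R not orthonormal (max |R'R - I| = {err:.3g})")
        det = np.linalg.det(self.R)
        if np.max(np.abs(det - 1.0)) > atol:
            raise ValueError("R contains improper rotations (det != +1)")

    def __len__(self) -> int:
        return self.times.size


@dataclass
class PoseSeries:
    """Yaw/pitch/roll orientation (radians) of one body part over time.

    Yaw is stored unwrapped (continuous across ±π); pitch is confined to
    [-π/2, π/2] by the yaw-pitch-roll convention.
    """

    times: np.ndarray
    fps: float
    part: Part
    yaw: np.ndarray
    pitch: np.ndarray
    roll: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        for name in ("yaw", "pitch", "roll"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != self.times.shape:
                raise ValueError(f"{name} must match times in shape")
            setattr(self, name, arr)
        _check_uniform_times(self.times, self.fps)
        if np.any(np.abs(self.pitch) > np.pi / 2 + 1e-9):
            raise ValueError("pitch outside [-pi/2, pi/2]")
        if np.any(np.abs(np.diff(self.yaw)) > np.pi):
            raise ValueError("yaw not unwrapped: jump > pi between frames")

    def __len__(self) -> int:
        return self.times.size

    def with_angles(self, yaw=None, pitch=None, roll=None) -> "PoseSeries":
        return replace(
            self,
            yaw=self.yaw if yaw is None else np.asarray(yaw, float),
            pitch=self.pitch if pitch is None else np.asarray(pitch, float),
            roll=self.roll if roll is None else np.asarray(roll, float),
        )


@dataclass
class VelocitySeries:
    """Body-frame angular velocity about the z axis, deg/s per frame."""

    times: np.ndarray
    fps: float
    part: Part
    omega_z: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.omega_z = np.asarray(self.omega_z, dtype=float)
        if self.omega_z.shape != self.times.shape:
            raise ValueError("omega_z must match times in shape")
        if np.any(~np.isfinite(self.omega_z)):
            raise ValueError("omega_z contains non-finite values")
        _check_uniform_times(self.times, self.fps)

    def __len__(self) -> int:
        return self.times.size


@dataclass
class LabelSeries:
    """Binary per-frame labels: 1 = saccade, 0 = intersaccade.

    Instances play three roles downstream: head ground truth H(t), thorax
    benchmark T(t) and classifier prediction C(t); ``role`` tags which.
    """

    times: np.ndarray
    labels: np.ndarray
    role: str = "labels"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.labels.shape != self.times.shape:
            raise ValueError("labels must match times in shape")
        if self.labels.size and not np.all(np.isin(self.labels, (0, 1))):
            raise ValueError("labels must be binary 0/1")
        self.labels = self.labels.astype(np.int8)

    def __len__(self) -> int:
        return self.times.size
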