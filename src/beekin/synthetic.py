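"""Synthetic head/thorax flights with known saccade ground truth.

The generator emulates the saccadic structure of bumblebee learning flights:
brief head yaw pulses (several tens of ms) separated by near-zero
intersaccades, with thorax pulses of equal angular integral that start
earlier, last longer and peak lower, plus temporally correlated measurement
noise. Event times, amplitudes and the head-thorax lag are known exactly, so
segmentation, classification and causality analyses can be validated without
recorded flights.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import cumulative_trapezoid

from . import kinematics as kin
from .segmentation import ThresholdPair, two_threshold_segment
from .series import (LabelSeries, MarkerFrameSeries, Part, PoseSeries,
                     VelocitySeries, time_grid)

__all__ = ["FlightConfig", "SyntheticFlight", "generate_flight",
           "markers_from_pose", "degrade"]


@dataclass
class FlightConfig:
    """Study conditions for one synthetic flight.

    Defaults give head saccades of ~40 ms (4 pulse SDs) whose peak velocities
    (~800-2400 deg/s) clear the 372.42 deg/s seed threshold, a thorax that
    turns through the same angle but earlier, broader and slower, and
    Ornstein-Uhlenbeck measurement noise that makes thorax traces harder to
    threshold than head traces.
    """

    duration: float = 10.0          # s
    fps: float = 500.0
    saccade_rate: float = 4.0       # events/s
    refractory: float = 200.0       # ms, minimum gap between events
    amplitude_deg: tuple[float, float] = (20.0, 60.0)  # |turn| range, sign random
    head_pulse_sd: float = 14.0     # ms, Gaussian velocity-pulse SD
    thorax_lead: float = 8.0        # ms, thorax pulse center precedes head's
    thorax_width_factor: float = 1.5
    noise_sd_head: float = 30.0     # deg/s
    noise_sd_thorax: float = 80.0   # deg/s
    noise_corr_ms: float = 20.0     # OU correlation time
    pitch_roll_amplitude: float = 0.0  # deg
    marker_side: float = 0.005      # m, equilateral marker triangle
    seed: int = 0

    def __post_init__(self) -> None:
        if self.refractory <= 4 * self.head_pulse_sd:
            raise ValueError("refractory must exceed 4*head_pulse_sd")
        if self.saccade_rate < 0 or self.duration <= 0 or self.marker_side <= 0:
            raise ValueError("rate, duration and marker_side must be positive")
        if self.saccade_rate > 0 and self.saccade_rate * self.refractory / 1000.0 >= 1.0:
            raise ValueError("saccade_rate infeasible for the refractory period")


@dataclass
class SyntheticFlight:
    """One generated flight: poses, velocities, ground truth and markers."""

    config: FlightConfig
    head_pose: PoseSeries
    thorax_pose: PoseSeries
    head_v: VelocitySeries
    thorax_v: VelocitySeries
    true_labels: LabelSeries
    events: list[tuple[float, float]]      # (time s, amplitude deg)
    head_markers: MarkerFrameSeries
    thorax_markers: MarkerFrameSeries
    clean_head_omega: np.ndarray = field(repr=False, default=None)
    clean_thorax_omega: np.ndarray = field(repr=False, default=None)


def _ou_noise(rng: np.random.Generator, n: int, dt: float, sd: float,
              corr_s: float) -> np.ndarray:
    if sd == 0:
        return np.zeros(n)
    a = np.exp(-dt / corr_s)
    x = np.empty(n)
    x[0] = rng.normal(0.0, sd)
    innov = rng.normal(0.0, sd * np.sqrt(1 - a * a), size=n - 1)
    for i in range(1, n):
        x[i] = a * x[i - 1] + innov[i - 1]
    return x


def _gauss_pulses(times: np.ndarray, centers: np.ndarray, amps: np.ndarray,
                  sd_s: float) -> np.ndarray:
    out = np.zeros_like(times)
    norm = 1.0 / (sd_s * np.sqrt(2 * np.pi))
    for c, a in zip(centers, amps):
        out += a * norm * np.exp(-0.5 * ((times - c) / sd_s) ** 2)
    return out


def generate_flight(cfg: FlightConfig | None = None, **overrides) -> SyntheticFlight:
    """Generate one flight, fully reproducible from ``cfg.seed``.

    Head angular velocity is a sum of Gaussian pulses (integral = signed
    saccade amplitude) plus OU noise; the thorax receives pulses of equal
    integral, centered ``thorax_lead`` ms earlier and ``thorax_width_factor``
    broader. Yaw is the cumulative integral of the (noisy) velocity, so pose
    and velocity stay mutually consistent; ground-truth labels come from the
    noise-free head velocity at the default hysteresis thresholds.
    """
    cfg = replace(cfg, **overrides) if cfg is not None else FlightConfig(**overrides)
    rng = np.random.default_rng(cfg.seed)
    fps = cfg.fps
    n = int(round(cfg.duration * fps))
    times = time_grid(n, fps)
    dt = 1.0 / fps

    sd_h = cfg.head_pulse_sd / 1000.0
    sd_t = sd_h * cfg.thorax_width_factor
    lead = cfg.thorax_lead / 1000.0
    margin = max(7 * sd_h, abs(lead) + 7 * sd_t)

    # renewal process: gaps = refractory + exponential, mean gap = 1/rate
    centers = []
    if cfg.saccade_rate > 0:
        r0 = cfg.refractory / 1000.0
        mean_exp = 1.0 / cfg.saccade_rate - r0
        t = margin + rng.uniform(0, 1.0 / cfg.saccade_rate)
        while t < cfg.duration - margin:
            centers.append(t)
            t += r0 + rng.exponential(mean_exp)
    centers = np.asarray(centers)
    amps = np.empty(0)
    if centers.size:
        lo, hi = cfg.amplitude_deg
        amps = rng.uniform(lo, hi, size=centers.size) * rng.choice(
            [-1.0, 1.0], size=centers.size)

    clean_head = _gauss_pulses(times, centers, amps, sd_h)
    clean_thorax = _gauss_pulses(times, centers - lead, amps, sd_t)

    noise_h = _ou_noise(rng, n, dt, cfg.noise_sd_head, cfg.noise_corr_ms / 1000.0)
    noise_t = _ou_noise(rng, n, dt, cfg.noise_sd_thorax, cfg.noise_corr_ms / 1000.0)

    deg2rad = np.pi / 180.0
    poses = {}
    for part, omega in (("head", clean_head + noise_h),
                        ("thorax", clean_thorax + noise_t)):
        yaw = cumulative_trapezoid(omega * deg2rad, times, initial=0.0)
        if cfg.pitch_roll_amplitude > 0:
            amp = cfg.pitch_roll_amplitude * deg2rad
            ph = rng.uniform(0, 2 * np.pi, size=2)
            pitch = amp * np.sin(2 * np.pi * 3.1 * times + ph[0])
            roll = amp * np.sin(2 * np.pi * 2.3 * times + ph[1])
        else:
            pitch = np.zeros(n)
            roll = np.zeros(n)
        poses[part] = PoseSeries(times=times, fps=fps, part=part, yaw=yaw,
                                 pitch=pitch, roll=roll)

    # "measured" velocities differentiate the pose, like the real pipeline
    head_v = kin.angular_velocity_z(poses["head"])
    thorax_v = kin.angular_velocity_z(poses["thorax"])

    true_labels = two_threshold_segment(
        VelocitySeries(times=times, fps=fps, part="head", omega_z=clean_head),
        ThresholdPair())
    true_labels.role = "head_truth"

    return SyntheticFlight(
        config=cfg,
        head_pose=poses["head"], thorax_pose=poses["thorax"],
        head_v=head_v, thorax_v=thorax_v,
        true_labels=true_labels,
        events=list(zip(centers.tolist(), amps.tolist())),
        head_markers=markers_from_pose(poses["head"], cfg.marker_side, "head"),
        thorax_markers=markers_from_pose(poses["thorax"], cfg.marker_side, "thorax"),
        clean_head_omega=clean_head, clean_thorax_omega=clean_thorax,
    )


def markers_from_pose(pose: PoseSeries, side: float = 0.005,
                      part: Part | None = None,
                      origin: np.ndarray | None = None) -> MarkerFrameSeries:
    """Place an equilateral marker triangle (front on +x, left/right symmetric
    about x, centroid at the origin) under each frame's rotation.

    ``origin`` is an optional (n, 3) translation path; default stationary.
    """
    n = len(pose)
    R = kin.ypr_to_rotation(pose.yaw, pose.pitch, pose.roll)
    s = side
    canon = {
        "front": np.array([s / np.sqrt(3.0), 0.0, 0.0]),
        "left": np.array([-s / (2 * np.sqrt(3.0)), s / 2.0, 0.0]),
        "right": np.array([-s / (2 * np.sqrt(3.0)), -s / 2.0, 0.0]),
    }
    if origin is None:
        origin = np.zeros((n, 3))
    pos = {k: origin + np.einsum("nij,j->ni", R, v) for k, v in canon.items()}
    return MarkerFrameSeries(times=pose.times, fps=pose.fps,
                             part=part or pose.part,
                             left=pos["left"], right=pos["right"],
                             front=pos["front"])


def degrade(flight: SyntheticFlight, fps_target: float,
            topview: bool = False) -> SyntheticFlight:
    """Emulate a degraded recording of an existing flight.

    Optionally flattens the markers to a top view (pitch/roll information
    lost), then decimates each pose to ``fps_target`` and spline-interpolates
    back to the original grid; velocities are recomputed from the degraded
    poses. Ground-truth labels stay on the original grid.
    """
    if fps_target > flight.config.fps:
        raise ValueError("fps_target must not exceed the recording fps")
    stride = max(1, int(round(flight.config.fps / fps_target)))
    if stride == 1 and not topview:
        return flight
    new_pose = {}
    for part, pose in (("head", flight.head_pose), ("thorax", flight.thorax_pose)):
        if topview:
            markers = markers_from_pose(pose, flight.config.marker_side, part)
            pose = kin.pose_from_markers(kin.flatten_to_topview(markers))
        new_pose[part] = kin.resample_roundtrip(pose, fps_target)
    return replace(
        flight,
        head_pose=new_pose["head"], thorax_pose=new_pose["thorax"],
        head_v=kin.angular_velocity_z(new_pose["head"]),
        thorax_v=kin.angular_velocity_z(new_pose["thorax"]),
        head_markers=markers_from_pose(new_pose["head"], flight.config.marker_side, "head"),
        thorax_markers=markers_from_pose(new_pose["thorax"], flight.config.marker_side, "thorax"),
    )
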