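"""CSV I/O, run manifests and the reproducible pipeline driver.

File conventions: UTF-8 CSV with a header row and '.' decimal; angles in
degrees on disk (radians internally); velocities in deg/s; times in seconds;
0-based frame indices and half-open intervals everywhere.
"""
from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import kinematics as kin
from .classifier import SaccadeClassifier, framerate_sweep
from .neuralmap import MapperConfig, VelocityMapper
from .segmentation import ThresholdPair, optimize_benchmark_thresholds, \
    segments_from_labels, two_threshold_segment
from .series import LabelSeries, MarkerFrameSeries, PoseSeries, VelocitySeries
from .synthetic import FlightConfig, generate_flight

log = logging.getLogger("beekin")

_RAD = np.pi / 180.0

STAGES = ("simulate", "orient", "segment", "benchmark", "train-clf",
          "sweep", "train-map", "shift-scan")


class SchemaError(ValueError):
    pass


def _infer_fps(t: np.ndarray, what: str) -> float:
    if t.size < 2:
        raise SchemaError(f"{what}: need at least 2 rows")
    dt = np.diff(t)
    if np.any(dt <= 0):
        line = int(np.flatnonzero(dt <= 0)[0]) + 2  # +1 header, +1 next row
        raise SchemaError(f"{what}: non-monotonic or duplicated time at line {line}")
    med = float(np.median(dt))
    if np.max(np.abs(dt - med)) > 1e-9:
        line = int(np.argmax(np.abs(dt - med))) + 2
        raise SchemaError(f"{what}: non-uniform time grid near line {line}")
    return 1.0 / med


def _read_csv(path, required, what):
    df = pd.read_csv(path)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what}: missing columns {missing}")
    bad = df[required].isna().any(axis=1)
    if bad.any():
        line = int(np.flatnonzero(bad.to_numpy())[0]) + 2
        raise SchemaError(f"{what}: NaN values at line {line}")
    return df


MARKER_COLS = ["t", "part", "lx", "ly", "lz", "rx", "ry", "rz", "fx", "fy", "fz"]


def read_markers_csv(path) -> dict[str, MarkerFrameSeries]:
    """Markers CSV → one MarkerFrameSeries per body part."""
    df = _read_csv(path, MARKER_COLS, "markers CSV")
    out = {}
    for part, g in df.groupby("part", sort=False):
        t = g["t"].to_numpy(float)
        fps = _infer_fps(t, f"markers CSV part={part}")
        out[str(part)] = MarkerFrameSeries(
            times=t, fps=fps, part=str(part),
            left=g[["lx", "ly", "lz"]].to_numpy(float),
            right=g[["rx", "ry", "rz"]].to_numpy(float),
            front=g[["fx", "fy", "fz"]].to_numpy(float))
    return out


def write_markers_csv(path, series_by_part: dict[str, MarkerFrameSeries]) -> None:
    frames = []
    for part, s in series_by_part.items():
        frames.append(pd.DataFrame({
            "t": s.times, "part": part,
            "lx": s.left[:, 0], "ly": s.left[:, 1], "lz": s.left[:, 2],
            "rx": s.right[:, 0], "ry": s.right[:, 1], "rz": s.right[:, 2],
            "fx": s.front[:, 0], "fy": s.front[:, 1], "fz": s.front[:, 2]}))
    pd.concat(frames).to_csv(path, index=False)


def read_pose_csv(path) -> dict[str, PoseSeries]:
    df = _read_csv(path, ["t", "part", "yaw_deg", "pitch_deg", "roll_deg"],
                   "pose CSV")
    out = {}
    for part, g in df.groupby("part", sort=False):
        t = g["t"].to_numpy(float)
        fps = _infer_fps(t, f"pose CSV part={part}")
        out[str(part)] = PoseSeries(
            times=t, fps=fps, part=str(part),
            yaw=np.unwrap(g["yaw_deg"].to_numpy(float) * _RAD),
            pitch=g["pitch_deg"].to_numpy(float) * _RAD,
            roll=g["roll_deg"].to_numpy(float) * _RAD)
    return out


def write_pose_csv(path, series_by_part: dict[str, PoseSeries]) -> None:
    frames = [pd.DataFrame({"t": s.times, "part": part,
                            "yaw_deg": s.yaw / _RAD,
                            "pitch_deg": s.pitch / _RAD,
                            "roll_deg": s.roll / _RAD})
              for part, s in series_by_part.items()]
    pd.concat(frames).to_csv(path, index=False)


def read_velocity_csv(path) -> dict[str, VelocitySeries]:
    df = _read_csv(path, ["t", "part", "omega_z_degps"], "velocity CSV")
    out = {}
    for part, g in df.groupby("part", sort=False):
        t = g["t"].to_numpy(float)
        fps = _infer_fps(t, f"velocity CSV part={part}")
        out[str(part)] = VelocitySeries(times=t, fps=fps, part=str(part),
                                        omega_z=g["omega_z_degps"].to_numpy(float))
    return out


def write_velocity_csv(path, series_by_part: dict[str, VelocitySeries]) -> None:
    frames = [pd.DataFrame({"t": s.times, "part": part,
                            "omega_z_degps": s.omega_z})
              for part, s in series_by_part.items()]
    pd.concat(frames).to_csv(path, index=False)


def read_labels_csv(path) -> LabelSeries:
    df = _read_csv(path, ["t", "label"], "labels CSV")
    t = df["t"].to_numpy(float)
    _infer_fps(t, "labels CSV")
    return LabelSeries(times=t, labels=df["label"].to_numpy(int))


def write_labels_csv(path, labels: LabelSeries) -> None:
    pd.DataFrame({"t": labels.times, "label": labels.labels}).to_csv(
        path, index=False)


# ---------------------------------------------------------------------------

def _digest(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


@dataclass
class RunManifest:
    """Reproducibility record of one pipeline run."""

    config: dict
    seed: int
    package_version: str
    input_digests: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)
    timings_s: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True, default=str)


def write_results(manifest: RunManifest, outputs: dict, out_dir) -> dict:
    """Write metric dicts as JSON and DataFrames as CSV, plus the manifest.

    Returns {name: path}. Overwrites idempotently.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = {}
    for name, obj in outputs.items():
        if isinstance(obj, pd.DataFrame):
            p = out_dir / f"{name}.csv"
            obj.to_csv(p, index=False)
        else:
            p = out_dir / f"{name}.json"
            p.write_text(json.dumps(obj, indent=2, sort_keys=True, default=str))
        manifest.outputs[name] = str(p)
        written[name] = p
    (out_dir / "manifest.json").write_text(manifest.to_json())
    return written


def run_pipeline(config: dict) -> RunManifest:
    """Execute the requested stages in dependency order on synthetic flights.

    ``config`` keys: ``stages`` (subset of STAGES), ``seed``, ``out``
    (output directory), ``n_flights``, ``flight`` (FlightConfig overrides),
    plus optional per-stage blocks ``classifier``, ``mapper``, ``sweep``.
    Unknown stages raise before any work.
    """
    from . import __version__

    stages = list(config.get("stages", STAGES))
    unknown = [s for s in stages if s not in STAGES]
    if unknown:
        raise ValueError(f"unknown stages: {unknown}")
    stages = [s for s in STAGES if s in stages]  # dependency order
    seed = int(config.get("seed", 0))
    out_dir = Path(config.get("out", "beekin_run"))
    manifest = RunManifest(config=config, seed=seed, package_version=__version__)
    outputs: dict = {}

    n_flights = int(config.get("n_flights", 6))
    fcfg = FlightConfig(**{**config.get("flight", {}), "seed": seed})
    flights = None

    def ensure_flights():
        nonlocal flights
        if flights is None:
            flights = [generate_flight(fcfg, seed=seed + i)
                       for i in range(n_flights)]
        return flights

    for stage in stages:
        t0 = time.perf_counter()
        log.info("stage %s: start", stage)
        if stage == "simulate":
            fl = ensure_flights()
            out_dir.mkdir(parents=True, exist_ok=True)
            for i, f in enumerate(fl):
                write_markers_csv(out_dir / f"flight{i}_markers.csv",
                                  {"head": f.head_markers,
                                   "thorax": f.thorax_markers})
                write_velocity_csv(out_dir / f"flight{i}_velocity.csv",
                                   {"head": f.head_v, "thorax": f.thorax_v})
                write_labels_csv(out_dir / f"flight{i}_labels.csv",
                                 f.true_labels)
            outputs["events"] = {f"flight{i}": f.events
                                 for i, f in enumerate(fl)}
        elif stage == "orient":
            fl = ensure_flights()
            for i, f in enumerate(fl):
                pose = {"head": kin.pose_from_markers(f.head_markers),
                        "thorax": kin.pose_from_markers(f.thorax_markers)}
                write_pose_csv(out_dir / f"flight{i}_pose.csv", pose)
        elif stage == "segment":
            fl = ensure_flights()
            segs = {}
            for i, f in enumerate(fl):
                lab = two_threshold_segment(f.head_v)
                segs[f"flight{i}"] = segments_from_labels(lab)
            outputs["segments"] = segs
        elif stage == "benchmark":
            fl = ensure_flights()
            v, lab = _pool(fl)
            thr, acc = optimize_benchmark_thresholds(v, lab)
            outputs["benchmark"] = {"high": thr.high, "low": thr.low,
                                    "accuracy": acc}
        elif stage == "train-clf":
            fl = ensure_flights()
            ccfg = config.get("classifier", {})
            res = SaccadeClassifier.from_flights(fl, seed=seed, **ccfg).fit()
            outputs["classifier"] = {"validation": res.validation,
                                     "test": res.test}
            manifest.outputs["classifier_summary"] = res.summary()
            config["_clf_results"] = res
        elif stage == "sweep":
            fl = ensure_flights()
            res = config.get("_clf_results")
            if res is None:
                res = SaccadeClassifier.from_flights(
                    fl, seed=seed, **config.get("classifier", {})).fit()
            scfg = config.get("sweep", {})
            fps_list = scfg.get("fps", [500, 250, 100, 50, 25])
            bench = outputs.get("benchmark")
            thr = (ThresholdPair(bench["high"], bench["low"])
                   if bench else ThresholdPair())
            outputs["sweep"] = framerate_sweep(
                fl, fps_list, res.model, thr,
                topview=bool(scfg.get("topview", False)))
        elif stage == "train-map":
            fl = ensure_flights()
            mcfg = config.get("mapper", {})
            cfg = MapperConfig(seed=seed, fps=fcfg.fps,
                               **{k: v for k, v in mcfg.items()
                                  if k != "direction"})
            res = VelocityMapper.from_flights(
                fl, mcfg.get("direction", "thorax2head"), cfg).fit()
            outputs["mapper"] = {"validation": res.validation,
                                 "test": res.test}
            config["_map_flights"] = fl
            config["_map_cfg"] = (mcfg.get("direction", "thorax2head"), cfg)
        elif stage == "shift-scan":
            fl = ensure_flights()
            direction, cfg = config.get(
                "_map_cfg", ("thorax2head",
                             MapperConfig(seed=seed, fps=fcfg.fps)))
            taus = config.get("shift_scan", {}).get(
                "tau_ms", list(range(-20, 21, 4)))
            outputs["shift_scan"] = VelocityMapper.from_flights(
                fl, direction, cfg).shift_scan(taus)
        manifest.timings_s[stage] = round(time.perf_counter() - t0, 3)
        log.info("stage %s: done in %.2fs", stage, manifest.timings_s[stage])

    for p in sorted(out_dir.glob("flight*_*.csv")):
        manifest.input_digests[p.name] = _digest(p)
    write_results(manifest, outputs, out_dir)
    return manifest


def _pool(flights):
    """Concatenate thorax velocities and head labels across flights onto a
    single artificial uniform grid (only frame-wise metrics use it)."""
    omega = np.concatenate([f.thorax_v.omega_z for f in flights])
    labels = np.concatenate([f.true_labels.labels for f in flights])
    fps = flights[0].config.fps
    t = np.arange(omega.size) / fps
    return (VelocitySeries(times=t, fps=fps, part="thorax", omega_z=omega),
            LabelSeries(times=t, labels=labels, role="head_truth"))
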