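"""Replication experiments on synthetic ensembles.

Each function runs one of the package's headline analyses end-to-end under
fixed study conditions on generated flights — the conditions the synthetic
generator encodes by default (500 fps, 8 ms thorax lead, OU measurement
noise) — and returns plain dicts/DataFrames of the measured quantities.
Problem sizes (flights × seconds, replicate counts, grid steps) are chosen so
a full run completes on one desktop CPU in a few minutes; docs/methods.md
discusses what that scale does and does not show.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .classifier import (SaccadeClassifier, _windows_for, framerate_sweep,
                         split_flights, topview_sweep)
from .neuralmap import MapperConfig, VelocityMapper
from .segmentation import optimize_benchmark_thresholds
from .series import LabelSeries, VelocitySeries
from .synthetic import FlightConfig, generate_flight

__all__ = ["classifier_vs_benchmark", "lag_recovery", "no_signal_control",
           "degradation_ensemble"]

# coarser optimizer grids for repeated-ensemble runs (default step is 5 deg/s)
_ENSEMBLE_HIGH_GRID = np.arange(200.0, 1000.0 + 1e-9, 10.0)
_ENSEMBLE_LOW_GRID = np.arange(50.0, 1000.0 + 1e-9, 10.0)


def _concat_split(split):
    omega = np.concatenate([v.omega_z for v, _ in split])
    labels = np.concatenate([lab.labels for v, lab in split])
    fps = split[0][0].fps
    t = np.arange(omega.size) / fps
    return (VelocitySeries(times=t, fps=fps, part="thorax", omega_z=omega),
            LabelSeries(times=t, labels=labels, role="head_truth"))


def classifier_vs_benchmark(seed: int, n_flights: int = 6,
                            duration: float = 10.0, n_trees: int = 100,
                            depth: int = 10, window_ms: float = 20.0) -> dict:
    """One replicate of the headline comparison: random forest vs the
    optimally thresholded thorax benchmark, on the validation frames.

    The benchmark thresholds are optimized directly on the validation frames
    (the most favorable treatment the benchmark can get); the forest never
    sees them during training.
    """
    flights = [generate_flight(FlightConfig(duration=duration),
                               seed=seed * 1009 + i) for i in range(n_flights)]
    pairs = [(f.thorax_v, f.true_labels) for f in flights]
    res = SaccadeClassifier(pairs, depth=depth, window_ms=window_ms,
                            n_trees=n_trees, seed=seed).fit()
    _, val, _ = split_flights(pairs)
    v_val, lab_val = _concat_split(val)
    thr, bench_acc = optimize_benchmark_thresholds(
        v_val, lab_val, _ENSEMBLE_HIGH_GRID, _ENSEMBLE_LOW_GRID)
    rf_acc = res.validation["accuracy"]
    return {"rf_accuracy": rf_acc, "benchmark_accuracy": bench_acc,
            "benchmark_high": thr.high, "benchmark_low": thr.low,
            "rf_auc": res.validation["auc"], "win": bool(rf_acc >= bench_acc)}


def lag_recovery(seed: int, lead_ms: float = 10.0, n_flights: int = 4,
                 duration: float = 6.0, tau_grid_ms=None,
                 window_ms: float = 5.0, n_hidden: int = 8) -> dict:
    """Shift-scan on flights where the head leads the thorax by ``lead_ms``.

    Head→thorax prediction should peak on the forecasting side at a shift of
    about ``lead_ms`` magnitude, and degrade on the backcasting side — the
    directionality signature the τ-scan is designed to expose.
    """
    if tau_grid_ms is None:
        tau_grid_ms = [float(t) for t in range(-16, 17, 2)]
    flights = [generate_flight(FlightConfig(duration=duration,
                                            thorax_lead=-lead_ms),
                               seed=seed * 2003 + i) for i in range(n_flights)]
    cfg = MapperConfig(n_hidden=n_hidden, window_ms=window_ms, seed=seed,
                       fps=flights[0].config.fps)
    table = VelocityMapper.from_flights(flights, "head2thorax",
                                        cfg).shift_scan(tau_grid_ms)
    peak_tau = float(table.loc[table["r"].idxmax(), "tau_ms"])
    fore = table[table["tau_ms"] < 0]["r"].max()
    back = table[table["tau_ms"] > 0]["r"].max()
    return {"table": table, "peak_tau_ms": peak_tau,
            "peak_magnitude_ms": abs(peak_tau),
            "asymmetric": bool(fore > back),
            "hit": bool(8.0 <= abs(peak_tau) <= 12.0 and fore > back)}


def no_signal_control(seed: int, n_flights: int = 4, duration: float = 6.0,
                      tau_grid_ms=(-8.0, 0.0, 8.0)) -> dict:
    """Negative control: source and target taken from *independent* flights.

    The mapper's r(τ) must hover near zero for every shift, and a classifier
    trained on unrelated labels must fall to the majority-class frequency.
    """
    a = [generate_flight(FlightConfig(duration=duration), seed=seed * 3001 + i)
         for i in range(n_flights)]
    b = [generate_flight(FlightConfig(duration=duration),
                         seed=seed * 3001 + 500 + i) for i in range(n_flights)]
    cfg = MapperConfig(n_hidden=8, window_ms=5.0, seed=seed,
                       fps=a[0].config.fps)
    table = VelocityMapper([f.head_v for f in a], [g.thorax_v for g in b],
                           cfg).shift_scan(list(tau_grid_ms))
    max_abs_r = float(np.nanmax(np.abs(table["r"])))

    pairs = [(fa.thorax_v, fb.true_labels) for fa, fb in zip(a, b)]
    res = SaccadeClassifier(pairs, n_trees=50, seed=seed).fit()
    train, val, _ = split_flights(pairs)
    ds_val = _windows_for(val, res.model.window)
    majority = float(max(np.mean(ds_val.y), 1 - np.mean(ds_val.y)))
    gap = float(res.validation["accuracy"] - majority)
    return {"table": table, "max_abs_r": max_abs_r,
            "classifier_accuracy": res.validation["accuracy"],
            "majority_rate": majority, "accuracy_gap": gap}


def degradation_ensemble(seeds, fps_list=(500.0, 250.0, 100.0, 50.0, 25.0),
                         n_flights: int = 3, duration: float = 6.0,
                         n_trees: int = 50) -> pd.DataFrame:
    """Classifier AUC vs frame rate over an ensemble of seeds, plus the
    exact top-view comparison at the default (pitch = roll = 0) conditions."""
    rows = []
    for seed in seeds:
        flights = [generate_flight(FlightConfig(duration=duration),
                                   seed=seed * 4001 + i)
                   for i in range(n_flights)]
        res = SaccadeClassifier.from_flights(flights, n_trees=n_trees,
                                             seed=seed).fit()
        sweep = framerate_sweep(flights, list(fps_list), res.model)
        sweep["seed"] = seed
        top = topview_sweep(flights, [fps_list[1]], res.model)
        sweep["topview_auc_diff_at_{:g}".format(fps_list[1])] = float(
            abs(top.loc[0, "classifier_auc"]
                - sweep.loc[sweep["fps"] == fps_list[1],
                            "classifier_auc"].iloc[0]))
        rows.append(sweep)
    return pd.concat(rows, ignore_index=True)
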