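"""Head-saccade classification from windowed thorax angular velocity.

A decision tree or random forest predicts the head's saccade/intersaccade
state at frame t from the thorax angular velocity in a window of width Δt
centered on t — the learned alternative to hard-thresholding the thorax
velocity (the benchmark). Exposed statsmodels-style: build a
:class:`SaccadeClassifier` from flights, ``fit()`` returns a
:class:`SaccadeClassifierResults` with metrics and ``summary()``.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.tree import DecisionTreeClassifier

from .segmentation import ThresholdPair, accuracy, two_threshold_segment
from .series import LabelSeries, VelocitySeries
from .synthetic import SyntheticFlight, degrade

__all__ = [
    "WindowSpec", "WindowedDataset", "ClassifierModel",
    "build_windows", "split_flights", "train_classifier",
    "grid_search_classifier", "evaluate_classifier",
    "framerate_sweep", "topview_sweep",
    "SaccadeClassifier", "SaccadeClassifierResults",
]


@dataclass(frozen=True)
class WindowSpec:
    """Centered window of thorax velocity samples.

    ``delta_t_ms`` is the total window width; the sample count is the odd
    integer 2*floor(Δt*fps/2000)+1, so the window is symmetric about the
    labeled frame and Δt=0 degenerates to the single center sample.
    """

    delta_t_ms: float
    fps: float = 500.0

    @property
    def n_samples(self) -> int:
        return 2 * int(np.floor(self.delta_t_ms * self.fps / 2000.0)) + 1

    @property
    def half_width(self) -> int:
        return (self.n_samples - 1) // 2


@dataclass
class WindowedDataset:
    """Design matrix of velocity windows with center-frame labels."""

    X: np.ndarray            # (rows, n_samples) deg/s
    y: np.ndarray            # (rows,) binary
    frame_index: np.ndarray  # center frame per row
    flight_id: np.ndarray    # provenance per row
    spec: WindowSpec

    def __len__(self) -> int:
        return self.X.shape[0]

    @staticmethod
    def concat(parts: list["WindowedDataset"]) -> "WindowedDataset":
        parts = [p for p in parts if len(p)]
        if not parts:
            raise ValueError("no non-empty datasets to concatenate")
        return WindowedDataset(
            X=np.vstack([p.X for p in parts]),
            y=np.concatenate([p.y for p in parts]),
            frame_index=np.concatenate([p.frame_index for p in parts]),
            flight_id=np.concatenate([p.flight_id for p in parts]),
            spec=parts[0].spec)


def build_windows(v: VelocitySeries, labels: LabelSeries, spec: WindowSpec,
                  flight_id: int = 0) -> WindowedDataset:
    """One row per frame with a complete centered window; edge frames within
    half a window of either end are dropped; y is the center-frame label."""
    if len(v) != len(labels):
        raise ValueError("velocity and labels must be aligned")
    n = spec.n_samples
    L = len(v)
    if L < n:
        warnings.warn("series shorter than the window: empty dataset",
                      RuntimeWarning, stacklevel=2)
        return WindowedDataset(X=np.empty((0, n)), y=np.empty(0, np.int8),
                               frame_index=np.empty(0, int),
                               flight_id=np.empty(0, int), spec=spec)
    X = sliding_window_view(v.omega_z, n).copy()
    h = spec.half_width
    centers = np.arange(h, L - h)
    return WindowedDataset(X=X, y=labels.labels[centers].copy(),
                           frame_index=centers,
                           flight_id=np.full(centers.size, flight_id), spec=spec)


def _slice_one(s, sl: slice):
    if isinstance(s, VelocitySeries):
        return VelocitySeries(times=s.times[sl], fps=s.fps, part=s.part,
                              omega_z=s.omega_z[sl])
    return LabelSeries(times=s.times[sl], labels=s.labels[sl], role=s.role)


def _slice(v, second, sl: slice):
    return _slice_one(v, sl), _slice_one(second, sl)


def split_flights(flights):
    """70/30 train/validation split over the first K-1 flights; the last
    flight is held out in full as the test set.

    Each flight is a pair whose first element is a VelocitySeries and whose
    second is either the aligned LabelSeries (classification) or another
    VelocitySeries (velocity mapping).

    The 70% boundary is floor(0.7*n) frames from the start of each flight
    (time-ordered, no shuffling — consecutive frames are highly correlated).
    """
    if len(flights) < 2:
        raise ValueError("need at least 2 flights to hold one out for testing")
    train, val = [], []
    for v, lab in flights[:-1]:
        cut = int(np.floor(0.7 * len(v)))
        train.append(_slice(v, lab, slice(0, cut)))
        val.append(_slice(v, lab, slice(cut, len(v))))
    test = [flights[-1]]
    return train, val, test


@dataclass
class ClassifierModel:
    """A fitted tree/forest together with its window specification."""

    family: str                   # 'decision_tree' | 'random_forest'
    depth: int
    window: WindowSpec
    n_trees: int
    seed: int
    estimator: object = field(repr=False)

    def predict(self, ds: WindowedDataset) -> np.ndarray:
        return self.estimator.predict(ds.X).astype(np.int8)

    def scores(self, ds: WindowedDataset) -> np.ndarray:
        proba = self.estimator.predict_proba(ds.X)
        classes = list(self.estimator.classes_)
        if 1 not in classes:
            return np.zeros(len(ds))
        return proba[:, classes.index(1)]


def train_classifier(ds: WindowedDataset, family: str = "random_forest",
                     depth: int = 10, n_trees: int = 100,
                     seed: int = 0, bootstrap: bool = True) -> ClassifierModel:
    """Fit a tree or forest on a windowed dataset; deterministic given seed."""
    if not 1 <= depth <= 20:
        raise ValueError("depth must lie in [1, 20]")
    ymin, ymax = ds.y.min(), ds.y.max()
    if ymin == ymax:
        raise ValueError("training data contains a single class")
    counts = np.bincount(ds.y, minlength=2)
    if max(counts) > 4 * max(min(counts), 1):
        warnings.warn("class imbalance above 4:1; accuracy may mislead",
                      RuntimeWarning, stacklevel=2)
    if family == "decision_tree":
        est = DecisionTreeClassifier(max_depth=depth, random_state=seed)
    elif family == "random_forest":
        est = RandomForestClassifier(n_estimators=n_trees, max_depth=depth,
                                     random_state=seed, bootstrap=bootstrap)
    else:
        raise ValueError(f"unknown family {family!r}")
    est.fit(ds.X, ds.y)
    return ClassifierModel(family=family, depth=depth, window=ds.spec,
                           n_trees=n_trees if family == "random_forest" else 1,
                           seed=seed, estimator=est)


def evaluate_classifier(model: ClassifierModel, ds: WindowedDataset) -> dict:
    """Accuracy, error rate and ROC AUC of a fitted model on a dataset."""
    if len(ds) == 0:
        raise ValueError("empty dataset")
    pred = model.predict(ds)
    acc = float(np.mean(pred == ds.y))
    out = {"accuracy": acc, "error_rate": 1.0 - acc}
    if ds.y.min() == ds.y.max():
        warnings.warn("single-class reference: AUC undefined",
                      RuntimeWarning, stacklevel=2)
        out["auc"] = None
    else:
        out["auc"] = float(roc_auc_score(ds.y, model.scores(ds)))
    return out


def _windows_for(flights, spec):
    return WindowedDataset.concat(
        [build_windows(v, lab, spec, flight_id=i)
         for i, (v, lab) in enumerate(flights)])


def grid_search_classifier(
    flights, family: str = "random_forest",
    D_grid=range(1, 21), delta_t_grid=range(0, 51, 2),
    n_trees: int = 100, seed: int = 0, fps: float | None = None,
):
    """Systematic (depth, Δt) search: train on the train split, score accuracy
    on the validation split; ties break toward smaller depth then smaller Δt.

    Returns ``(best_model, table)`` with one table row per grid cell.
    """
    D_grid = list(D_grid)
    delta_t_grid = list(delta_t_grid)
    if not D_grid or not delta_t_grid:
        raise ValueError("grids must be non-empty")
    train, val, _ = split_flights(flights)
    fps = fps or flights[0][0].fps
    rows = []
    best = None
    for dt in delta_t_grid:
        spec = WindowSpec(delta_t_ms=dt, fps=fps)
        ds_train = _windows_for(train, spec)
        ds_val = _windows_for(val, spec)
        for D in D_grid:
            model = train_classifier(ds_train, family=family, depth=D,
                                     n_trees=n_trees, seed=seed)
            metrics = evaluate_classifier(model, ds_val)
            rows.append({"depth": D, "delta_t_ms": dt, **metrics})
            key = (metrics["accuracy"], -D, -dt)
            if best is None or key > best[0]:
                best = (key, model)
    table = pd.DataFrame(rows)
    return best[1], table


# ---------------------------------------------------------------------------
# degradation sweeps over synthetic flights

def framerate_sweep(flights: list[SyntheticFlight], fps_list,
                    model: ClassifierModel,
                    benchmark_thr: ThresholdPair | None = None,
                    topview: bool = False) -> pd.DataFrame:
    """Classifier vs. benchmark AUC on the held-out flight as the recording
    degrades to lower frame rates (and optionally to a top view).

    Poses are decimated and spline-restored, velocities recomputed, and both
    methods scored against the full-rate head ground truth. The benchmark
    keeps the thresholds it was given (optimized at the full rate).
    """
    benchmark_thr = benchmark_thr or ThresholdPair()
    test = flights[-1]
    rows = []
    for fps in fps_list:
        deg = degrade(test, fps, topview=topview)
        labels = test.true_labels
        ds = build_windows(deg.thorax_v, labels, model.window)
        clf_auc = float(roc_auc_score(ds.y, model.scores(ds)))
        bench = two_threshold_segment(deg.thorax_v, benchmark_thr)
        bench_auc = float(roc_auc_score(labels.labels, bench.labels.astype(float)))
        bench_acc = accuracy(bench, labels)
        clf_acc = float(np.mean(model.predict(ds) == ds.y))
        rows.append({"fps": fps, "topview": topview,
                     "classifier_auc": clf_auc, "classifier_accuracy": clf_acc,
                     "benchmark_auc": bench_auc, "benchmark_accuracy": bench_acc})
    return pd.DataFrame(rows)


def topview_sweep(flights, fps_list, model, benchmark_thr=None) -> pd.DataFrame:
    """``framerate_sweep`` under the null-pitch/roll (single top camera)
    assumption."""
    return framerate_sweep(flights, fps_list, model, benchmark_thr, topview=True)


# ---------------------------------------------------------------------------
# model / results façade

class SaccadeClassifier:
    """Model object: head-saccade classifier over a set of flights.

    Parameters
    ----------
    flights : list of (VelocitySeries, LabelSeries)
        Thorax velocity and head ground-truth labels per flight, full-rate.
        The last flight is held out for testing.
    family : 'random_forest' or 'decision_tree'
    depth, window_ms, n_trees, seed : hyperparameters (see the field's
        conventions: depth in [1, 20], window width in ms).
    """

    def __init__(self, flights, family="random_forest", depth=10,
                 window_ms=20.0, n_trees=100, seed=0):
        self.flights = flights
        self.family = family
        self.depth = depth
        self.window_ms = window_ms
        self.n_trees = n_trees
        self.seed = seed

    @classmethod
    def from_flights(cls, flights: list[SyntheticFlight], **kw):
        """Build from SyntheticFlight objects (thorax velocity → head truth)."""
        pairs = [(f.thorax_v, f.true_labels) for f in flights]
        return cls(pairs, **kw)

    def fit(self) -> "SaccadeClassifierResults":
        train, val, test = split_flights(self.flights)
        spec = WindowSpec(self.window_ms, fps=self.flights[0][0].fps)
        ds_train = _windows_for(train, spec)
        model = train_classifier(ds_train, family=self.family, depth=self.depth,
                                 n_trees=self.n_trees, seed=self.seed)
        return SaccadeClassifierResults(
            model=model,
            validation=evaluate_classifier(model, _windows_for(val, spec)),
            test=evaluate_classifier(model, _windows_for(test, spec)),
            n_train=len(ds_train))


@dataclass
class SaccadeClassifierResults:
    """Fitted classifier with validation/test metrics."""

    model: ClassifierModel
    validation: dict
    test: dict
    n_train: int

    def predict_labels(self, v: VelocitySeries,
                       labels: LabelSeries) -> LabelSeries:
        ds = build_windows(v, labels, self.model.window)
        return LabelSeries(times=v.times[ds.frame_index],
                           labels=self.model.predict(ds), role="classifier")

    def summary(self) -> str:
        m = self.model
        lines = [
            "Head-saccade classifier",
            "=" * 45,
            f"family        : {m.family}",
            f"depth         : {m.depth}",
            f"window        : {m.window.delta_t_ms} ms "
            f"({m.window.n_samples} samples @ {m.window.fps:g} fps)",
            f"trees         : {m.n_trees}",
            f"train rows    : {self.n_train}",
            "-" * 45,
        ]
        for name, d in (("validation", self.validation), ("test", self.test)):
            auc = "n/a" if d["auc"] is None else f"{d['auc']:.4f}"
            lines.append(f"{name:<11} accuracy {d['accuracy']:.4f}  "
                         f"error {100 * d['error_rate']:.2f}%  AUC {auc}")
        return "\n".join(lines)
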