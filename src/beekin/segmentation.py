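"""Two-threshold (hysteresis) saccade segmentation and the benchmark.

Frames whose |ω_z| exceeds the high threshold seed a saccade; the saccade
extends over the contiguous neighbors where |ω_z| still exceeds the low
threshold. The defaults (372.42 / 200.54 deg/s) are the manually determined
head-velocity thresholds that define the ground truth; the *benchmark*
re-optimizes a threshold pair on the thorax velocity to best match the head
labels — the baseline any learned classifier must beat.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .series import LabelSeries, VelocitySeries

__all__ = [
    "ThresholdPair",
    "two_threshold_segment",
    "accuracy",
    "optimize_benchmark_thresholds",
    "segments_from_labels",
    "DEFAULT_HIGH_GRID",
    "DEFAULT_LOW_GRID",
]

DEFAULT_HIGH_GRID = np.arange(200.0, 1000.0 + 1e-9, 5.0)
DEFAULT_LOW_GRID = np.arange(50.0, 1000.0 + 1e-9, 5.0)


@dataclass(frozen=True)
class ThresholdPair:
    """Hysteresis thresholds in deg/s: ``high`` seeds a saccade, ``low``
    extends it. Defaults are the head ground-truth values."""

    high: float = 372.42
    low: float = 200.54

    def __post_init__(self) -> None:
        if not 0 < self.low <= self.high:
            raise ValueError(
                f"need 0 < low <= high, got low={self.low}, high={self.high}")


def _hysteresis(mag: np.ndarray, high: float, low: float) -> np.ndarray:
    above_low = mag > low
    seeds = mag > high
    if not seeds.any():
        return np.zeros(mag.shape, dtype=np.int8)
    comp, n = ndimage.label(above_low)
    keep = np.zeros(n + 1, dtype=bool)
    keep[np.unique(comp[seeds])] = True
    keep[0] = False
    return keep[comp].astype(np.int8)


def two_threshold_segment(
    v: VelocitySeries, thr: ThresholdPair | None = None, *, signed: bool = False
) -> LabelSeries:
    """Hysteresis segmentation of a velocity trace into saccade frames.

    By default thresholds apply to |ω_z| (saccades turn both ways); with
    ``signed=True`` only positive excursions count.
    """
    thr = thr or ThresholdPair()
    mag = v.omega_z if signed else np.abs(v.omega_z)
    return LabelSeries(times=v.times, labels=_hysteresis(mag, thr.high, thr.low))


def accuracy(pred: LabelSeries, ref: LabelSeries) -> float:
    """Fraction of frames on which the two label series agree."""
    if len(pred) != len(ref):
        raise ValueError(
            f"label series lengths differ: {len(pred)} vs {len(ref)}")
    return float(np.mean(pred.labels == ref.labels))


def optimize_benchmark_thresholds(
    v_thorax: VelocitySeries,
    head_labels: LabelSeries,
    high_grid=None,
    low_grid=None,
) -> tuple[ThresholdPair, float]:
    """Exhaustive grid search for the thorax threshold pair that best matches
    the head ground truth.

    Only pairs with low <= high are considered; ties break toward the largest
    high, then the largest low, so the result is deterministic.
    """
    high_grid = DEFAULT_HIGH_GRID if high_grid is None else np.asarray(high_grid, float)
    low_grid = DEFAULT_LOW_GRID if low_grid is None else np.asarray(low_grid, float)
    if high_grid.size == 0 or low_grid.size == 0:
        raise ValueError("threshold grids must be non-empty")
    if len(v_thorax) != len(head_labels):
        raise ValueError("velocity and labels must be aligned")
    if head_labels.labels.size and head_labels.labels.min() == head_labels.labels.max():
        warnings.warn("head labels are all-constant: threshold optimum is "
                      "degenerate", RuntimeWarning, stacklevel=2)
    mag = np.abs(v_thorax.omega_z)
    ref = head_labels.labels.astype(np.int64)
    N = ref.size
    P = int(ref.sum())
    highs = np.sort(np.unique(high_grid))
    best = None
    # For a fixed low, the connected components of {|w| > low} are fixed; a
    # component is predicted saccade iff its max |w| exceeds high. Cumulative
    # sums over components sorted by peak give every high in O(C).
    for low in np.sort(np.unique(low_grid)):
        hs = highs[highs >= low]
        if hs.size == 0:
            continue
        comp, n = ndimage.label(mag > low)
        if n == 0:
            accs = np.full(hs.size, (N - P) / N)
        else:
            idx = np.arange(1, n + 1)
            peak = ndimage.maximum(mag, comp, idx)
            ones = ndimage.sum_labels(ref, comp, idx)
            size = ndimage.sum_labels(np.ones(N), comp, idx)
            order = np.argsort(peak)[::-1]  # strongest component first
            cum_ones = np.concatenate(([0.0], np.cumsum(ones[order])))
            cum_size = np.concatenate(([0.0], np.cumsum(size[order])))
            # number of kept components = #{peak > high}
            k = n - np.searchsorted(peak[order][::-1], hs, side="right")
            accs = (N - P + 2 * cum_ones[k] - cum_size[k]) / N
        for high, acc in zip(hs, accs):
            cand = (acc, high, low)
            if best is None or cand > best:
                best = cand
    if best is None:
        raise ValueError("no candidate pair satisfies low <= high")
    acc, high, low = best
    return ThresholdPair(high=float(high), low=float(low)), float(acc)


def segments_from_labels(labels: LabelSeries) -> list[tuple[int, int]]:
    """Maximal runs of saccade frames as half-open (start, end) index pairs."""
    lab = labels.labels
    if lab.size == 0:
        return []
    edges = np.diff(np.concatenate(([0], lab, [0])))
    starts = np.flatnonzero(edges == 1)
    ends = np.flatnonzero(edges == -1)
    return list(zip(starts.tolist(), ends.tolist()))
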