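"""Quick-look figures. matplotlib is imported lazily (optional dependency)."""
from __future__ import annotations

from .synthetic import SyntheticFlight

__all__ = ["plot_flight", "plot_shift_scan", "plot_sweep"]


def _axes(ax, nrows=1):
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(nrows, 1, sharex=(nrows > 1))
    return ax


def plot_flight(flight: SyntheticFlight, ax=None):
    """Head/thorax ω_z traces with ground-truth saccades shaded."""
    axes = _axes(ax, nrows=2)
    t = flight.head_v.times
    for a, v, name in zip(axes, (flight.head_v, flight.thorax_v),
                          ("head", "thorax")):
        a.plot(t, v.omega_z, lw=0.6)
        lab = flight.true_labels.labels.astype(bool)
        a.fill_between(t, *a.get_ylim(), where=lab, alpha=0.15, color="C3",
                       label="head saccade")
        a.set_ylabel(f"{name} $\\omega_z$ (deg/s)")
    axes[-1].set_xlabel("time (s)")
    return axes


def plot_shift_scan(table, ax=None):
    """r(τ) curve from ``correlation_vs_shift`` / ``shift_scan``."""
    ax = _axes(ax)
    ax.plot(table["tau_ms"], table["r"], marker="o")
    ax.axvline(0.0, color="k", lw=0.5)
    ax.set_xlabel(r"temporal shift $\tau$ (ms)   [$\tau<0$: forecasting]")
    ax.set_ylabel("prediction-target correlation r")
    return ax


def plot_sweep(table, ax=None):
    """Classifier vs benchmark AUC across frame rates (``framerate_sweep``)."""
    ax = _axes(ax)
    ax.plot(table["fps"], table["classifier_auc"], marker="o",
            label="classifier")
    ax.plot(table["fps"], table["benchmark_auc"], marker="s",
            label="benchmark")
    ax.set_xscale("log")
    ax.set_xlabel("frame rate (fps)")
    ax.set_ylabel("AUC vs head ground truth")
    ax.legend()
    return ax
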