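"""Quick-look plots for order selection, tuning and fatigue trajectories."""

from __future__ import annotations

import numpy as np

from .fatigue import FatigueMetrics
from .nmf import OrderSelection
from .tuning import TuningResult

__all__ = ["plot_vaf_curve", "plot_tuning", "plot_fatigue_metrics"]


def _get_ax(ax):
    if ax is None:
        import matplotlib.pyplot as plt

        _, ax = plt.subplots()
    return ax


def plot_vaf_curve(selection: OrderSelection, ax=None):
    """Global and worst-muscle VAF against candidate synergy count."""
    ax = _get_ax(ax)
    curve = selection.curve
    ax.plot(curve["order"], curve["global_vaf"], "o-", label="global VAF")
    ax.plot(curve["order"], curve["min_local_vaf"], "s--", label="min local VAF")
    ax.axhline(0.90, color="grey", lw=0.8)
    ax.axhline(0.80, color="grey", lw=0.8, ls=":")
    ax.axvline(selection.order, color="C3", lw=0.8)
    ax.set_xlabel("number of synergies")
    ax.set_ylabel("VAF")
    ax.legend()
    return ax


def plot_tuning(result: TuningResult, synergy: int = 0, ax=None):
    """Activation against angle to the preferred direction for one synergy."""
    ax = _get_ax(ax)
    s = result.synergies[synergy]
    angles = np.array([s.angle_to(q) for q in s.directions])
    order = np.argsort(angles)
    ax.plot(angles[order], s.activations[order], "o-")
    ax.set_xlabel("angle to PD (deg)")
    ax.set_ylabel("activation coefficient")
    return ax


def plot_fatigue_metrics(metrics: FatigueMetrics, channel: int = 0, ax=None):
    """Normalized median frequency and RMS of one channel across epochs."""
    ax = _get_ax(ax)
    epochs = np.arange(1, metrics.mf_normalized.shape[1] + 1)
    ax.plot(epochs, metrics.mf_normalized[channel], "o-", label="median frequency")
    ax.plot(epochs, metrics.rms_normalized[channel], "s--", label="RMS amplitude")
    ax.axhline(100.0, color="grey", lw=0.8)
    ax.set_xlabel("epoch")
    ax.set_ylabel("% of epoch 1")
    ax.legend()
    return ax
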