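"""Minimal quick-look figures (optional; nothing else imports this)."""

from __future__ import annotations

import numpy as np


def plot_raster(raster, ax=None, max_points: int = 50000):
    """Spike raster, TC below RE, one dot per spike."""
    import matplotlib.pyplot as plt

    ax = ax or plt.gca()
    rows = raster.to_rows()
    if rows.shape[0] > max_points:
        rows = rows[:: rows.shape[0] // max_points + 1]
    tc_hi = raster.populations["TC"][1]
    colors = np.where(rows[:, 0] < tc_hi, "tab:blue", "tab:red")
    ax.scatter(rows[:, 1], rows[:, 0], s=1, c=colors, linewidths=0)
    ax.set_xlabel("time (ms)")
    ax.set_ylabel("neuron")
    return ax


def plot_mf_trajectory(traj, ax=None):
    """Mean rates with +-1 sd bands from the covariance diagonal."""
    import matplotlib.pyplot as plt

    ax = ax or plt.gca()
    t = traj["t"]
    for pop, col in (("e", "tab:blue"), ("i", "tab:red")):
        nu = traj[f"nu_{pop}"]
        sd = np.sqrt(np.maximum(traj[f"c_{pop}{pop}"], 0.0))
        ax.plot(t, nu, color=col, label=f"nu_{pop}")
        ax.fill_between(t, nu - sd, nu + sd, color=col, alpha=0.2, linewidth=0)
    ax.set_xlabel("time (ms)")
    ax.set_ylabel("rate (Hz)")
    ax.legend()
    return ax
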