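"""Figure-style plots for sweeps, diversity trends and trial time series."""

from __future__ import annotations

import numpy as np

from .analysis import DiversityResult, SweepResult
from .trial import TrialRecord


def _get_axes(ax=None):
    if ax is not None:
        return ax
    import matplotlib.pyplot as plt

    _, ax = plt.subplots()
    return ax


def plot_offset_series(sweep: SweepResult, ax=None):
    """Body-offset series of the sweep trials; the [-1, 1] band marks where
    simultaneous mutual contact is possible."""
    ax = _get_axes(ax)
    for value, rec in sweep:
        ax.plot(np.arange(1, rec.steps + 1), rec.offset, lw=0.8, label=f"u2 = {value:+.1f}")
    ax.axhspan(-1, 1, color="0.9", zorder=0)
    ax.set_xlabel("time step")
    ax.set_ylabel("body offset  D1 + D2")
    ax.legend(fontsize="small")
    return ax


def plot_link_distances(sweep: SweepResult, ax=None):
    """D1 (solid) and D2 (dashed) series for each sweep trial."""
    ax = _get_axes(ax)
    for value, rec in sweep:
        t = np.arange(1, rec.steps + 1)
        (line,) = ax.plot(t, rec.d[:, 0], lw=0.8, label=f"u2 = {value:+.1f}")
        ax.plot(t, rec.d[:, 1], lw=0.8, ls="--", color=line.get_color())
    ax.set_xlabel("time step")
    ax.set_ylabel("link distance D")
    ax.legend(fontsize="small")
    return ax


def plot_diversity(result: DiversityResult, ax=None):
    """Pooled link-distance sd with its best-fit linear trend."""
    ax = _get_axes(ax)
    t = np.arange(1, result.sd_series.shape[0] + 1)
    ax.plot(t, result.sd_series, lw=0.7)
    ax.plot(t, result.intercept + result.slope * t, "k--", lw=1.5,
            label=f"slope = {result.slope:.3g} / step")
    ax.set_xlabel("time step")
    ax.set_ylabel("sd of pooled link distances")
    ax.legend()
    return ax


def plot_trial_timeseries(record: TrialRecord, max_steps: int | None = 1800):
    """Four-row panel per agent: positions, contact + motor output, link
    distance, and button-neuron outputs with the 0.75 click threshold."""
    import matplotlib.pyplot as plt

    T = record.steps if max_steps is None else min(record.steps, max_steps)
    t = np.arange(1, T + 1)
    fig, axes = plt.subplots(4, 2, figsize=(10, 9), sharex=True)
    for a in (0, 1):
        axes[0, a].plot(t, record.rf[:T, a], label="RF")
        axes[0, a].plot(t, record.bo[:T, a], label="BO")
        axes[0, a].set_title(f"agent {a + 1}")
        axes[0, a].set_ylabel("position")
        axes[0, a].legend(fontsize="small")
        axes[1, a].plot(t, 2 * record.outputs[:T, a, 1] - 1, color="0.5", lw=0.7)
        c = record.contacts[:T, a].astype(bool)
        axes[1, a].plot(t[c], np.ones(c.sum()), ".k", ms=2)
        axes[1, a].set_ylabel("contact / motor")
        axes[2, a].plot(t, record.d[:T, a])
        axes[2, a].set_ylabel("link distance D")
        axes[3, a].plot(t, record.outputs[:T, a, 2], label="left")
        axes[3, a].plot(t, record.outputs[:T, a, 3], label="right")
        axes[3, a].axhline(0.75, color="k", lw=0.8, ls=":")
        axes[3, a].set_ylabel("button output")
        axes[3, a].set_xlabel("time step")
        axes[3, a].legend(fontsize="small")
    fig.tight_layout()
    return fig
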