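"""Diagnostic figures: stress-response trajectories, GR sweeps, associations."""

from __future__ import annotations

import numpy as np

__all__ = ["plot_trajectory", "plot_sweep_gr", "plot_association"]


def _get_ax(ax):
    if ax is None:
        import matplotlib.pyplot as plt

        _, ax = plt.subplots()
    return ax


def plot_trajectory(traj, ax=None, components=("O", "O_G")):
    """Plasma GC (and optionally other species) through the stress response."""
    ax = _get_ax(ax)
    for c in components:
        ax.plot(traj.t, traj.component(c), label=c)
    for entry in traj.event_log:
        e = entry["event"]
        ax.axvline(e.time, color="grey", ls=":", lw=0.8)
        ax.annotate(e.target, (e.time, ax.get_ylim()[1]), fontsize=8,
                    ha="center", va="bottom")
    ax.set_xlabel("time (min)")
    ax.set_ylabel("concentration")
    ax.legend()
    return ax


def plot_sweep_gr(sweep, ax=None, classes=("baseline", "stress_induced", "post_dex", "post_acth")):
    """GC level at each sampling class as a function of GR abundance."""
    ax = _get_ax(ax)
    g = sweep.frame["G_tot"]
    for c in classes:
        ax.plot(g, sweep.frame[c], marker="o", ms=3, label=c)
    ax.set_xscale("log")
    ax.set_xlabel("total GR abundance")
    ax.set_ylabel("plasma GC")
    ax.legend()
    return ax


def plot_association(table, ax=None):
    """Response magnitude vs single-timepoint GC for each sampling time."""
    ax = _get_ax(ax)
    for t in table.sampling_times:
        ax.scatter(table.frame[f"gc_{t:g}min"], table.frame["response_magnitude"],
                   s=12, alpha=0.6, label=f"t = {t:g} min")
    ax.set_xlabel("plasma GC at sampling time")
    ax.set_ylabel("response magnitude (peak GC-GR complex)")
    ax.legend()
    return ax
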