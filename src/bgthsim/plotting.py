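"""Figure generation: regional voltage panels and phase trajectories.

These reproduce the layouts used to inspect simulation regimes — a
four-panel stack of the regional membrane voltages with the SMC pulse
train under the thalamic panel, and voltage-vs-voltage phase portraits
of two regions.  They are visual artifacts only; every quantitative
statement about a run comes from :mod:`bgthsim.analysis`.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .analysis import phase_trajectory
from .engine import SimResult
from .regions import REGIONS, SMCParams, smc_input


def plot_voltages(result: SimResult, smc: SMCParams | None = None,
                  title: str | None = None):
    """Four stacked regional voltage traces (TH last, with SMC overlay)."""
    order = ["TH", "STN", "GPe", "GPi"]
    fig, axes = plt.subplots(len(order), 1, figsize=(10, 8), sharex=True)
    for ax, region in zip(axes, order):
        ax.plot(result.time, result.region_trace(region), lw=0.6,
                color="steelblue")
        ax.set_ylabel(f"{region}\n(mV)")
        if region == "TH" and smc is not None:
            pulses = np.array([smc_input(t, smc) for t in result.time])
            ax.plot(result.time, pulses * 4 - 95, color="red", lw=0.6,
                    label="SMC input")
            ax.legend(loc="upper right", fontsize=8)
    axes[-1].set_xlabel("time (ms)")
    if title:
        fig.suptitle(title)
    fig.tight_layout()
    return fig


def plot_phase(result: SimResult, x_region: str, y_region: str,
               window: tuple | None = None):
    """Phase portrait of two regional voltages."""
    traj = phase_trajectory(result, x_region, y_region, window)
    fig, ax = plt.subplots(figsize=(6, 6))
    ax.plot(traj.x, traj.y, lw=0.4, color="black")
    ax.set_xlabel(f"{x_region} voltage (mV)")
    ax.set_ylabel(f"{y_region} voltage (mV)")
    fig.tight_layout()
    return fig


def plot_raster(result: SimResult):
    """Micro-network spike raster, one band per region."""
    fig, ax = plt.subplots(figsize=(10, 6))
    offset = 0
    yticks, ylabels = [], []
    n = result.meta.get("n_micro", 50)
    for region in REGIONS:
        arr = result.spikes.get(region)
        if arr is not None and len(arr):
            ax.scatter(arr[:, 1], arr[:, 0] + offset, s=0.5, marker="|")
        yticks.append(offset + n / 2)
        ylabels.append(region)
        offset += n
    ax.set_yticks(yticks, ylabels)
    ax.set_xlabel("time (ms)")
    fig.tight_layout()
    return fig
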