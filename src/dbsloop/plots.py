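"""Figure helpers for simulation and sweep outputs."""
from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402
import pandas as pd  # noqa: E402

__all__ = ["plot_membrane_raster", "plot_tracking", "plot_sweep_bars"]


def plot_membrane_raster(t, v, path: str | Path,
                         title: str = "TH membrane potentials") -> None:
    """Heat map of per-neuron membrane potentials over time."""
    fig, ax = plt.subplots(figsize=(8, 3))
    im = ax.imshow(np.asarray(v).T, aspect="auto", origin="lower",
                   extent=[t[0], t[-1], 0.5, v.shape[1] + 0.5],
                   cmap="viridis")
    ax.set(xlabel="t (ms)", ylabel="neuron", title=title)
    fig.colorbar(im, ax=ax, label="v (mV)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_tracking(t, x, x_d, u, path: str | Path, neuron: int = 0) -> None:
    """Reference vs plant trace and control input for one TH neuron."""
    fig, axes = plt.subplots(3, 1, figsize=(8, 6), sharex=True)
    axes[0].plot(t, x_d[:, neuron], lw=0.8, label="healthy reference")
    axes[0].plot(t, x[:, neuron], lw=0.8, ls="--", label="PD + DBS")
    axes[0].set_ylabel("v (mV)")
    axes[0].legend(loc="upper right", fontsize=8)
    axes[1].plot(t, np.abs(x_d[:, neuron] - x[:, neuron]), lw=0.8)
    axes[1].set_ylabel("|e| (mV)")
    axes[1].set_yscale("log")
    tu = t[:u.shape[0]]
    axes[2].plot(tu, u[:, neuron], lw=0.8)
    axes[2].set(xlabel="t (ms)", ylabel="u (uA/cm$^2$)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_sweep_bars(summary: pd.DataFrame, path: str | Path) -> None:
    """Mean +- SD bars of RMSE and Energy per controller and uncertainty."""
    fig, axes = plt.subplots(1, 2, figsize=(10, 4))
    width = 0.35
    levels = sorted(summary["uncertainty"].unique())
    xs = np.arange(len(levels))
    for k, metric in enumerate(("rmse", "energy")):
        for i, ctrl in enumerate(("aftsmc", "afsmc")):
            sub = summary[summary["controller"] == ctrl].sort_values("uncertainty")
            mean = sub[(metric, "mean")].to_numpy()
            sd = sub[(metric, "std")].to_numpy()
            axes[k].bar(xs + (i - 0.5) * width, mean, width, yerr=sd,
                        capsize=3, label=ctrl.upper())
        axes[k].set(xticks=xs, xticklabels=[f"{lv:.0%}" for lv in levels],
                    xlabel="uncertainty", ylabel=metric)
        axes[k].legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
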