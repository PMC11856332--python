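"""Optional matplotlib renderings of trajectories, phase maps and boundaries."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
from matplotlib.colors import BoundaryNorm, ListedColormap

from .simulate import Trajectory
from .sweep import PhaseMap

__all__ = ["plot_trajectory", "plot_phase_map", "plot_boundaries"]

_WINNER_COLORS = ["#bbbbbb", "#4477aa", "#ccbb44", "#ee6677"]  # extinct, 1, 2, 3


def plot_trajectory(traj: Trajectory, path) -> None:
    """Compartment counts over time, log-friendly linear scale."""
    fig, ax = plt.subplots(figsize=(7, 4.5))
    df = traj.to_dataframe()
    for col in df.columns[1:]:
        ax.plot(df["year"], df[col], label=col, lw=1)
    ax.set_xlabel("year")
    ax.set_ylabel("individuals")
    ax.legend(ncol=2, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_phase_map(pm: PhaseMap, path) -> None:
    """Winner per (mu, nu1) cell; asterisks mark migrant-dominated cells."""
    fig, ax = plt.subplots(figsize=(6, 5))
    cmap = ListedColormap(_WINNER_COLORS)
    norm = BoundaryNorm(np.arange(-0.5, 4), cmap.N)
    mesh = ax.pcolormesh(
        pm.mu_values, pm.nu1_values, pm.winners, cmap=cmap, norm=norm, shading="nearest"
    )
    for i, nu1 in enumerate(pm.nu1_values):
        for j, mu in enumerate(pm.mu_values):
            if pm.migrants_dominate[i, j]:
                ax.text(mu, nu1, "*", ha="center", va="center", fontsize=12)
    cbar = fig.colorbar(mesh, ticks=[0, 1, 2, 3])
    cbar.set_label("winning strain (0 = extinct)")
    ax.set_xlabel(r"immunity loss rate $\mu$")
    ax.set_ylabel(r"Habitat 1 recovery rate $\nu_1$")
    ax.set_title(rf"$\delta_I$ = {pm.delta_I:g}")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_boundaries(curves, path) -> None:
    """1->2 and 2->3 transition thresholds vs mu, one line style per delta_I."""
    fig, axes = plt.subplots(1, 2, figsize=(9, 4), sharey=True)
    for curve in curves:
        axes[0].plot(curve.mu_values, curve.nu1_at_1to2, marker="o",
                     label=rf"$\delta_I$={curve.delta_I:g}")
        axes[1].plot(curve.mu_values, curve.nu1_at_2to3, marker="o",
                     label=rf"$\delta_I$={curve.delta_I:g}")
    axes[0].set_title("strain 1 → 2")
    axes[1].set_title("strain 2 → 3")
    for ax in axes:
        ax.set_xlabel(r"immunity loss rate $\mu$")
        ax.legend(fontsize=8)
    axes[0].set_ylabel(r"transition recovery rate $\nu_1$")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
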