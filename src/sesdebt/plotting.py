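"""Figure rendering for branch diagrams, SOS maps, ghost passages and
perturbation experiments.

Every figure is drawn from the same arrays that the CSV exporters write, so
figures are regenerable from disk artifacts alone.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .bifurcation import BifurcationDiagram
from .sos import SOSMap
from .transients import PerturbationRecord, Trajectory, speed_profile

__all__ = [
    "plot_branch_diagram",
    "plot_sos_map",
    "plot_ghost_passage",
    "plot_perturbation",
]

_STYLE = {"stable": dict(ls="-", lw=2), "unstable": dict(ls="--", lw=1.5), "marginal": dict(ls=":", lw=1.5)}
_REGION_LEVEL = {"III": 0, "II": 1, "I": 2}
_REGION_COLOR = {"III": "#b2182b", "II": "#fddbc7", "I": "#2166ac"}


def _plot_branch(ax, x, y, stability, color, label):
    stability = np.asarray(stability, dtype=object)
    for kind, style in _STYLE.items():
        mask = stability == kind
        if mask.any():
            yy = np.where(mask, y, np.nan)
            ax.plot(x, yy, color=color, label=f"{label} ({kind})", **style)


def plot_branch_diagram(diagram: BifurcationDiagram, path: str | Path) -> Path:
    """Equilibrium branches of R* and P* over c0 (in multiples of r)."""
    fig, axes = plt.subplots(1, 2, figsize=(10, 4), sharex=True)
    x = diagram.c0_over_r
    colors = {"extended": "tab:green", "baseline": "tab:gray"}
    for variant, branches in diagram.branches.items():
        color = colors.get(variant, "tab:blue")
        for branch in ("interior-high", "interior-low"):
            arrs = branches[branch]
            _plot_branch(axes[0], x, arrs["R"], arrs["stability"], color, f"{variant} {branch}")
            _plot_branch(axes[1], x, arrs["P"], arrs["stability"], color, f"{variant} {branch}")
    if diagram.fold is not None:
        c0f, Rf = diagram.fold
        axes[0].plot([c0f / diagram.params.r], [Rf], marker="*", ms=14, color="magenta",
                     zorder=5, label="fold")
    axes[0].set_ylabel("R* (resource units km$^{-2}$)")
    axes[1].set_ylabel("P* (people km$^{-2}$)")
    for ax in axes:
        ax.set_xlabel("c0 / r")
    axes[0].legend(fontsize=7, loc="best")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def plot_sos_map(sos: SOSMap, path: str | Path) -> Path:
    """Region heatmap over the (c0, h) grid; legend lists present labels only."""
    fig, ax = plt.subplots(figsize=(6, 4.5))
    levels = np.vectorize(_REGION_LEVEL.get)(sos.labels)
    ax.pcolormesh(
        sos.c0,
        sos.h,
        levels.T,
        cmap=matplotlib.colors.ListedColormap(
            [_REGION_COLOR[k] for k in ("III", "II", "I")]
        ),
        vmin=-0.5,
        vmax=2.5,
        shading="nearest",
    )
    present = sorted(set(sos.labels.ravel()), key=_REGION_LEVEL.get)
    handles = [plt.Rectangle((0, 0), 1, 1, color=_REGION_COLOR[k]) for k in present]
    ax.legend(handles, present, title="region", loc="upper left", fontsize=8)
    ax.set_xlabel("c0 (year$^{-1}$)")
    ax.set_ylabel("h (resource units person$^{-1}$ year$^{-1}$)")
    ax.set_title(f"safe operating space — {sos.variant}")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def plot_ghost_passage(traj: Trajectory, ghost: np.ndarray, path: str | Path) -> Path:
    """Time series plus a speed-coloured state-space path past the ghost."""
    if traj.speed is None:
        try:
            speed_profile(traj)
        except ValueError:
            pass
    fig = plt.figure(figsize=(10, 7))
    labels = ("P (people km$^{-2}$)", "R (resource units km$^{-2}$)", "S (species)")
    order = (1, 0, 2)
    for panel, (idx, lab) in enumerate(zip(order, labels)):
        ax = fig.add_subplot(2, 3, panel + 1)
        ax.plot(traj.times, traj.states[:, idx], color="k", lw=1)
        ax.axhline(ghost[idx], color="magenta", ls="--", lw=1)
        ax.set_xlabel("time (years)")
        ax.set_ylabel(lab)
    ax = fig.add_subplot(2, 1, 2)
    if traj.speed is not None:
        mid = 0.5 * (traj.states[1:] + traj.states[:-1])
        sc = ax.scatter(mid[:, 0], mid[:, 1], c=traj.speed, cmap="inferno", s=6)
        fig.colorbar(sc, ax=ax, label=r"log(1 + (|$\Delta$P|+|$\Delta$R|+|$\Delta$S|)/$\Delta$t)")
    else:
        ax.plot(traj.states[:, 0], traj.states[:, 1], color="k", lw=1)
    ax.plot([ghost[0]], [ghost[1]], marker="o", ms=12, color="magenta", label="ghost")
    ax.set_xlabel("R")
    ax.set_ylabel("P")
    ax.legend(loc="best", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def plot_perturbation(record: PerturbationRecord, path: str | Path) -> Path:
    """Perturbed vs counterfactual (grey) runs, extended and no-debt variants."""
    fig, axes = plt.subplots(3, 1, figsize=(7, 8), sharex=True)
    pre, post, cf = record.pre, record.post, record.counterfactual_post
    qs = record.quasistatic_post
    for idx, (ax, lab) in enumerate(zip(axes, ("P", "R", "S"))):
        ax.plot(cf.times, cf.states[:, idx if idx < cf.states.shape[1] else 0],
                color="0.6", lw=1.5, label="no perturbation")
        ax.plot(pre.times, pre.states[:, idx], color="k", lw=1)
        ax.plot(post.times, post.states[:, idx], color="k", lw=1, label="perturbed (extended)")
        if idx < 2:
            ax.plot(qs.times, qs.states[:, idx], color="tab:blue", lw=1, ls="--",
                    label="perturbed (no debt)")
        ax.axvline(record.t_pert, color="r", ls=":", lw=1)
        ax.set_ylabel(lab)
    axes[0].legend(fontsize=8, loc="best")
    axes[-1].set_xlabel("time (years)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)
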