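"""Figure exports: trajectory envelopes, likelihood curves, bifurcation
diagrams and sweep curves. File-only (Agg backend); plotting failures never
touch data outputs."""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .bifurcation import BifurcationDiagram
from .model import VARIABLES
from .readout import LikelihoodCurve
from .scenarios import SweepResult
from .simulate import EnsembleSummary, Trajectory

__all__ = ["plot_trajectory", "plot_ensemble", "plot_likelihood",
           "plot_bifurcation", "plot_sweep"]

_COLORS = {"A": "#c0392b", "R": "#7f8c8d", "T": "#2980b9", "P": "#27ae60"}


def plot_trajectory(traj: Trajectory, out: Path, title: Optional[str] = None) -> Path:
    fig, ax = plt.subplots(figsize=(5, 3.2))
    for i, v in enumerate(VARIABLES):
        ax.plot(traj.times, traj.states[:, i], label=v, color=_COLORS[v])
    ax.set(xlabel="time (days)", ylabel="concentration", title=title)
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(out, dpi=150)
    plt.close(fig)
    return Path(out)


def plot_ensemble(summary: EnsembleSummary, out: Path, title: Optional[str] = None) -> Path:
    fig, ax = plt.subplots(figsize=(5, 3.2))
    for i, v in enumerate(VARIABLES):
        ax.plot(summary.times, summary.median[:, i], label=v, color=_COLORS[v])
        ax.fill_between(summary.times, summary.lower[:, i], summary.upper[:, i],
                        color=_COLORS[v], alpha=0.2, linewidth=0)
    ax.set(xlabel="time (days)", ylabel="concentration", title=title)
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(out, dpi=150)
    plt.close(fig)
    return Path(out)


def plot_likelihood(curve: LikelihoodCurve, out: Path, title: Optional[str] = None) -> Path:
    fig, ax = plt.subplots(figsize=(5, 3.2))
    ax.plot(curve.times, curve.values, color="k")
    for level, style in ((0.95, ":"), (0.5, "--"), (0.05, ":")):
        ax.axhline(level, color="gray", linestyle=style, linewidth=0.8)
    ax.set(xlabel="time (days)", ylabel="MN differentiation likelihood",
           ylim=(-0.02, 1.02), title=title)
    fig.tight_layout()
    fig.savefig(out, dpi=150)
    plt.close(fig)
    return Path(out)


def plot_bifurcation(diagram: BifurcationDiagram, out: Path,
                     title: Optional[str] = None) -> Path:
    """Stable branches solid, unstable dashed, folds marked."""
    fig, ax = plt.subplots(figsize=(5, 3.2))
    pts = diagram.points
    stable = pts[pts["stable"]]
    unstable = pts[~pts["stable"]]
    ax.plot(stable["R"], stable["T_star"], ".", ms=2, color="k", label="stable")
    ax.plot(unstable["R"], unstable["T_star"], ".", ms=2, color="k",
            alpha=0.3, label="unstable")
    for fp in diagram.fold_points:
        ax.axvline(fp.R, color="#c0392b", linestyle="--", linewidth=0.8)
    ax.set(xlabel="GliR", ylabel="Tgfβ steady state", title=title)
    ax.legend(frameon=False, markerscale=4)
    fig.tight_layout()
    fig.savefig(out, dpi=150)
    plt.close(fig)
    return Path(out)


def plot_sweep(result: SweepResult, out: Path, quantity: str = "delta_t",
               title: Optional[str] = None) -> Path:
    fig, ax = plt.subplots(figsize=(5, 3.2))
    for variant, sub in result.table.groupby("variant"):
        sub = sub.sort_values("value")
        ax.plot(sub["value"], sub[quantity], marker="o", ms=3, label=variant)
    ax.set(xlabel=result.parameter, ylabel=f"{quantity} (days)", title=title)
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(out, dpi=150)
    plt.close(fig)
    return Path(out)
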