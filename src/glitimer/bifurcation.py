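"""Steady states of the Tgfβ equation and hysteresis (fold) analysis.

At frozen Gli levels (A, R) the Tgfβ dynamics reduce to the scalar ODE
dT/dt = v_T·g(T) with

    g(T) = (1−ω_TT)·Hʷ⁺(A,h_AT,ω_AT)·Hʷ⁻(R,h_RT,ω_RT)
           + ω_TT·H⁺(T,h_TT) − T .

Because g(0) ≥ 0 and g(1) ≤ 0 there is always at least one root in [0, 1].
Roots are located by sign-change scanning on a fine T grid followed by
bisection refinement; a root is stable iff g'(T) < 0. With Tgfβ
self-activation strong enough (the hysteretic parameter row) the system is
bistable over a GliR window: as R decays below the fold R_up the low-T
branch disappears and T jumps to the high branch, which is self-sustaining
— the switch is one-way.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .model import ModelConfig, hill_pos, weighted_hill_neg, weighted_hill_pos

__all__ = ["BifurcationDiagram", "FoldPoint", "t_steady_states", "sweep_R"]


def _production(T, A: float, R: float, config: ModelConfig):
    w, h, n = config.weights, config.thresholds, config.hill_coefficient
    base = (1.0 - w.omega_TT) * (
        weighted_hill_pos(A, h.h_AT, w.omega_AT, n)
        * weighted_hill_neg(R, h.h_RT, w.omega_RT, n)
    )
    if w.omega_TT > 0:
        return base + w.omega_TT * hill_pos(T, h.h_TT, n)
    return base + np.zeros_like(np.asarray(T, dtype=float))


def t_steady_states(
    A: float,
    R: float,
    config: ModelConfig,
    n_grid: int = 10_000,
    xtol: float = 1e-10,
) -> List[Tuple[float, bool]]:
    """All roots T* ∈ [0, 1] of g(T) with stability labels (True = stable)."""
    if A < 0 or R < 0:
        raise ValueError("frozen Gli levels must be >= 0")
    Tg = np.linspace(0.0, 1.0, n_grid + 1)
    g = _production(Tg, A, R, config) - Tg

    roots: List[float] = []
    for i in np.where(np.sign(g[:-1]) * np.sign(g[1:]) < 0)[0]:
        roots.append(
            brentq(lambda T: float(_production(T, A, R, config) - T),
                   Tg[i], Tg[i + 1], xtol=xtol)
        )
    # grid points that are (numerically) exact roots
    for i in np.where(g == 0.0)[0]:
        roots.append(float(Tg[i]))
    roots = sorted(roots)

    out: List[Tuple[float, bool]] = []
    dT = 1e-7
    for T0 in roots:
        lo, hi = max(T0 - dT, 0.0), min(T0 + dT, 1.0)
        slope = (
            float(_production(hi, A, R, config) - hi)
            - float(_production(lo, A, R, config) - lo)
        ) / (hi - lo)
        out.append((T0, slope < 0))
    return out


@dataclass(frozen=True)
class FoldPoint:
    """R value at which the number of steady states changes.

    ``kind`` records which branch appears/disappears as R decreases:
    ``"up"`` = low-T branch vanishes (the system jumps up),
    ``"down"`` = high-T branch vanishes (the system would fall back).
    """

    R: float
    kind: str


@dataclass
class BifurcationDiagram:
    """Steady-state branches of Tgfβ against GliR with fold points."""

    points: pd.DataFrame  # columns R, T_star, stable
    fold_points: List[FoldPoint] = field(default_factory=list)
    A_policy: str = "off"

    @property
    def r_up(self) -> Optional[float]:
        ups = [f.R for f in self.fold_points if f.kind == "up"]
        return max(ups) if ups else None

    @property
    def r_down(self) -> Optional[float]:
        downs = [f.R for f in self.fold_points if f.kind == "down"]
        return max(downs) if downs else None

    def n_roots(self, R: float) -> int:
        sub = self.points["R"].to_numpy()
        i = np.argmin(np.abs(sub - R))
        return int((self.points["R"] == sub[i]).sum())

    def to_frame(self) -> pd.DataFrame:
        return self.points.copy()


def _A_of_R(R: float, A_policy) -> float:
    if A_policy == "off":
        return 1.0  # value irrelevant when omega_AT = 0
    if A_policy == "equal":
        return R
    return float(A_policy)  # frozen numeric A


def _classify_change(before: List[Tuple[float, bool]], after: List[Tuple[float, bool]]) -> str:
    """Kind of fold between adjacent R values with different root counts.

    The fold merges a stable/unstable branch pair; the branch that survives
    on the one-root side identifies the pair: if the surviving root matches
    the highest root of the multi-root side, the low and middle branches
    merged ("up" fold — the jump taken as R decays); if it matches the
    lowest, the middle and high branches merged ("down" fold).
    """
    many, few = (before, after) if len(before) > len(after) else (after, before)
    m = sorted(T for T, _ in many)
    surviving = sorted(T for T, _ in few)[0]
    nearest = min(range(len(m)), key=lambda i: abs(m[i] - surviving))
    return "up" if nearest == len(m) - 1 else "down"


def sweep_R(
    config: ModelConfig,
    R_values: Optional[np.ndarray] = None,
    A_policy="off",
    n_grid: int = 10_000,
    refine_tol: float = 1e-6,
) -> BifurcationDiagram:
    """Bifurcation diagram of T* versus GliR.

    ``A_policy``: ``"off"`` (GliA link absent / ignored), ``"equal"`` (A
    slaved to R, the parallel-gradient assumption for the full network), or
    a fixed numeric A.
    """
    if R_values is None:
        R_values = np.linspace(0.0, 1.0, 401)
    R_values = np.asarray(R_values, dtype=float)

    rows = []
    counts = []
    roots_at = []
    for R in R_values:
        ss = t_steady_states(_A_of_R(R, A_policy), R, config, n_grid=n_grid)
        roots_at.append(ss)
        counts.append(len(ss))
        for T0, stab in ss:
            rows.append((R, T0, stab))
    counts = np.asarray(counts)

    folds: List[FoldPoint] = []
    order = np.argsort(R_values)[::-1]  # scan downward in R
    for j in range(len(order) - 1):
        i_hi, i_lo = order[j], order[j + 1]
        if counts[i_hi] == counts[i_lo]:
            continue
        lo_R, hi_R = R_values[i_lo], R_values[i_hi]
        n_target = counts[i_hi]
        # bisect the R location of the root-count change
        while hi_R - lo_R > refine_tol:
            mid = 0.5 * (lo_R + hi_R)
            n_mid = len(t_steady_states(_A_of_R(mid, A_policy), mid, config, n_grid=n_grid))
            if n_mid == n_target:
                hi_R = mid
            else:
                lo_R = mid
        kind = _classify_change(roots_at[i_hi], roots_at[i_lo])
        folds.append(FoldPoint(R=0.5 * (lo_R + hi_R), kind=kind))

    points = pd.DataFrame(rows, columns=["R", "T_star", "stable"])
    return BifurcationDiagram(points=points, fold_points=folds,
                              A_policy=str(A_policy))
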