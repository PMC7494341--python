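"""Canonical network presets, mutant configurations and parameter sweeps.

The five canonical parameterisations (one per regulatory-network variant)
are:

======================  =====================================================
``direct``              GliA → Phox2b (no Tgfβ arm), h_AP = 0.25
``relay``               GliR ⊣ Tgfβ ⊣ Phox2b, h_RT = 0.15
``self_activation``     relay plus weak Tgfβ self-activation (ω_TT = 0.4)
``hysteresis``          relay plus strong self-activation (ω_TT = 0.94),
                        a bistable, effectively one-way switch
``WT``                  full network: both Gli inputs plus the hysteretic
                        Tgfβ arm (the wild-type configuration)
======================  =====================================================

Mutants are derived from ``WT``: ``Tgfbr1_KO`` removes Tgfβ signalling to
Phox2b (ω_TP = 0); ``Gli1_KO`` starts with 30% less GliA (A(0) = 0.7);
``Gli1ON_Tgfbr1_KO`` additionally clamps GliA at its initial value
(λ_A = 0), so Phox2b production never shuts down and the cell never leaves
the motor-neuron state.

Shared rates: λ_A = λ_R = 0.86/day, v_T = 50/day, v_P = 90/day. The
package's reference noise levels are ε = 0.2 (kinetic) and η = 1
(threshold); both are conventions, see docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .lattice import simulate_lattice
from .model import (
    HillThresholds,
    KineticRates,
    ModelConfig,
    NetworkWeights,
    NoiseSettings,
    SystemState,
    quasi_steady_P,
)
from .readout import LikelihoodCurve, ReadoutModel, SwitchStatistics, likelihood_path, switch_statistics
from .simulate import Trajectory, integrate_ode, run_ensemble

__all__ = [
    "PRESET_NAMES",
    "ScenarioPreset",
    "SweepResult",
    "make_preset",
    "run_mutant_panel",
    "sweep",
]

DEFAULT_EPSILON = 0.2
DEFAULT_ETA = 1.0

_TABLE_ROWS: Dict[str, Tuple[NetworkWeights, HillThresholds]] = {
    "direct": (
        NetworkWeights(omega_AP=1.0),
        HillThresholds(h_AP=0.25),
    ),
    "relay": (
        NetworkWeights(omega_RT=1.0, omega_TP=1.0),
        HillThresholds(h_RT=0.15, h_TP=0.3),
    ),
    "self_activation": (
        NetworkWeights(omega_RT=1.0, omega_TT=0.4, omega_TP=1.0),
        HillThresholds(h_RT=0.1, h_TT=0.3, h_TP=0.3),
    ),
    "hysteresis": (
        NetworkWeights(omega_RT=1.0, omega_TT=0.94, omega_TP=1.0),
        HillThresholds(h_RT=0.2, h_TT=0.3, h_TP=0.3),
    ),
    "WT": (
        NetworkWeights(omega_AT=1.0, omega_RT=1.0, omega_TT=0.94, omega_AP=1.0, omega_TP=1.0),
        HillThresholds(h_AT=0.08, h_RT=0.2, h_TT=0.3, h_AP=0.08, h_TP=0.3),
    ),
}

_MUTANTS = ("Tgfbr1_KO", "Gli1_KO", "Gli1ON_Tgfbr1_KO")
PRESET_NAMES: Tuple[str, ...] = tuple(_TABLE_ROWS) + _MUTANTS

_ALIASES = {
    "full": "WT",
    "full_wt": "WT",
    "wt": "WT",
    "tgfbr1_ko": "Tgfbr1_KO",
    "gli1_ko": "Gli1_KO",
    "gli1on_tgfbr1_ko": "Gli1ON_Tgfbr1_KO",
}


def _base_config(name: str, epsilon: float, eta: float, correlated_AR: bool,
                 A0: float = 1.0, lambda_A: float = 0.86) -> ModelConfig:
    weights, thresholds = _TABLE_ROWS[name]
    P0 = quasi_steady_P(A0, weights, thresholds)
    return ModelConfig(
        weights=weights,
        thresholds=thresholds,
        rates=KineticRates(lambda_A=lambda_A, lambda_R=0.86, v_T=50.0, v_P=90.0),
        noise=NoiseSettings(epsilon=epsilon, eta=eta, correlated_AR=correlated_AR),
        initial_state=SystemState(A=A0, R=1.0, T=0.0, P=P0),
    )


def make_preset(
    name: str,
    epsilon: float = DEFAULT_EPSILON,
    eta: float = DEFAULT_ETA,
    correlated_AR: bool = False,
) -> ModelConfig:
    """Build the canonical configuration for a network variant or mutant."""
    key = _ALIASES.get(name.lower(), name)
    if key in _TABLE_ROWS:
        return _base_config(key, epsilon, eta, correlated_AR)
    if key == "Tgfbr1_KO":
        wt = _base_config("WT", epsilon, eta, correlated_AR)
        return replace(wt, weights=replace(wt.weights, omega_TP=0.0))
    if key == "Gli1_KO":
        return _base_config("WT", epsilon, eta, correlated_AR, A0=0.7)
    if key == "Gli1ON_Tgfbr1_KO":
        cfg = _base_config("WT", epsilon, eta, correlated_AR, lambda_A=0.0)
        return replace(cfg, weights=replace(cfg.weights, omega_TP=0.0))
    raise ValueError(
        f"unknown preset {name!r}; available presets: {', '.join(PRESET_NAMES)}"
    )


@dataclass
class ScenarioPreset:
    """A named preset together with the overrides that define it."""

    name: str
    config: ModelConfig
    overrides: Dict[str, object]


@dataclass
class PanelEntry:
    name: str
    config: ModelConfig
    curve: LikelihoodCurve
    stats: SwitchStatistics


def run_mutant_panel(
    names: Sequence[str] = ("WT",) + _MUTANTS,
    readout: Optional[ReadoutModel] = None,
    seed: Optional[int] = None,
    n_replicates: int = 0,
) -> Dict[str, PanelEntry]:
    """Likelihood curves and switch statistics for a set of presets.

    With ``n_replicates`` = 0 (default) the panel is deterministic (single
    ODE path per preset); otherwise each preset is run as a seeded ensemble
    and the population likelihood is reported.
    """
    readout = readout or ReadoutModel(eta=DEFAULT_ETA)
    out: Dict[str, PanelEntry] = {}
    for i, name in enumerate(names):
        cfg = make_preset(name)
        if n_replicates > 0:
            if seed is None:
                raise ValueError("seed is required for stochastic panels")
            summ = run_ensemble(cfg, n_replicates, base_seed=seed + i)
            curve = likelihood_path(summ, readout)
        else:
            curve = likelihood_path(integrate_ode(cfg, record_every=10), readout)
        out[name] = PanelEntry(name=name, config=cfg, curve=curve,
                               stats=switch_statistics(curve))
    return out


@dataclass
class SweepResult:
    """Transition statistics across a parameter grid, one row per
    (network variant, parameter value)."""

    parameter: str
    table: pd.DataFrame
    n_replicates: int
    base_seed: Optional[int]
    options: Dict[str, object]

    def delta_t(self, variant: str) -> np.ndarray:
        sub = self.table[self.table["variant"] == variant]
        return sub.sort_values("value")["delta_t"].to_numpy(dtype=float)

    def t_switch(self, variant: str) -> np.ndarray:
        sub = self.table[self.table["variant"] == variant]
        return sub.sort_values("value")["t_switch"].to_numpy(dtype=float)


def _run_point(
    cfg: ModelConfig,
    readout: ReadoutModel,
    n_replicates: int,
    seed,
    spatial_averaging: bool,
    lattice_shape: Tuple[int, int],
) -> LikelihoodCurve:
    if spatial_averaging:
        lat = simulate_lattice(cfg, rows=lattice_shape[0], cols=lattice_shape[1],
                               seed=seed, coupling=True)
        return likelihood_path(lat.as_ensemble(), readout)
    if cfg.noise.epsilon > 0:
        summ = run_ensemble(cfg, n_replicates, base_seed=seed)
        return likelihood_path(summ, readout)
    return likelihood_path(integrate_ode(cfg, record_every=10), readout)


def sweep(
    parameter: str,
    grid: Iterable[float],
    variants: Sequence[str] = ("direct", "relay", "self_activation", "hysteresis"),
    n_replicates: int = 1000,
    base_seed: int = 0,
    epsilon: Optional[float] = None,
    eta: Optional[float] = None,
    spatial_averaging: bool = False,
    correlated_AR: bool = False,
    lattice_shape: Tuple[int, int] = (20, 20),
) -> SweepResult:
    """Δt / switch-time sweep over one of ``eta``, ``epsilon`` or ``lambda``.

    The non-swept noise level defaults to 0 for ``eta`` and ``lambda``
    sweeps (deterministic dynamics, the readout supplies the stochasticity)
    and to the reference η = 1 readout for ``epsilon`` sweeps; pass
    ``epsilon``/``eta`` explicitly to override. No-switch grid points are
    recorded with ``censored = True`` rather than dropped.
    """
    if parameter not in ("eta", "epsilon", "lambda"):
        raise ValueError("parameter must be one of 'eta', 'epsilon', 'lambda'")
    grid = list(grid)
    if len(grid) < 3:
        raise ValueError("grid must contain at least 3 values")
    children = np.random.SeedSequence(base_seed).spawn(len(variants) * len(grid))
    rows = []
    for i, variant in enumerate(variants):
        for j, value in enumerate(grid):
            eps = epsilon if epsilon is not None else (0.0 if parameter != "epsilon" else DEFAULT_EPSILON)
            eta_val = eta if eta is not None else DEFAULT_ETA
            if parameter == "eta":
                eta_val = value
            cfg = make_preset(variant, epsilon=eps, correlated_AR=correlated_AR)
            if parameter == "epsilon":
                cfg = replace(cfg, noise=replace(cfg.noise, epsilon=float(value)))
            elif parameter == "lambda":
                cfg = replace(cfg, rates=replace(cfg.rates, lambda_A=float(value),
                                                 lambda_R=float(value)))
            readout = ReadoutModel(eta=eta_val)
            curve = _run_point(cfg, readout, n_replicates,
                               children[i * len(grid) + j], spatial_averaging,
                               lattice_shape)
            stats = switch_statistics(curve)
            rows.append({
                "variant": variant,
                "parameter": parameter,
                "value": float(value),
                "delta_t": stats.delta_t,
                "t_switch": stats.t_switch,
                "t_95": stats.t_95,
                "t_05": stats.t_05,
                "censored": stats.delta_t is None,
                "flags": ";".join(stats.flags),
            })
    table = pd.DataFrame(rows)
    return SweepResult(
        parameter=parameter, table=table, n_replicates=n_replicates,
        base_seed=base_seed,
        options={
            "spatial_averaging": spatial_averaging,
            "correlated_AR": correlated_AR,
            "lattice_shape": lattice_shape,
            "epsilon": epsilon,
            "eta": eta,
        },
    )
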