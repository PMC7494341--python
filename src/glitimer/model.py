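"""Core types and right-hand side of the Gli/Tgfβ/Phox2b timer network.

The model tracks four dimensionless concentrations: the Gli activator ``A``
and repressor ``R`` (both decaying exponentially from 1), the diffusible,
self-activating repressor Tgfβ ``T`` and the motor-neuron determinant
Phox2b ``P`` (both confined to [0, 1] by construction of their
production/decay terms).

Regulatory links are encoded by weighted Hill functions

    H⁺(x, h) = xⁿ / (hⁿ + xⁿ)        H⁻(x, h) = hⁿ / (hⁿ + xⁿ)
    Hʷ±(x, h, ω) = (1 − ω) + ω·H±(x, h)

with Hill coefficient n = 2 throughout. A weight ω = 0 removes the link
(the factor is identically 1 and the paired threshold is never read); ω = 1
recovers the plain Hill function.

The dynamical system is

    dA/dt = −λ_A·A
    dR/dt = −λ_R·R
    dT/dt = v_T·[ (1−ω_TT)·Hʷ⁺(A,h_AT,ω_AT)·Hʷ⁻(R,h_RT,ω_RT)
                  + ω_TT·H⁺(T_eff,h_TT) − T ]
    dP/dt = v_P·[ Hʷ⁺(A,h_AP,ω_AP)·Hʷ⁻(T_eff,h_TP,ω_TP) − P ]

``T_eff`` is the Tgfβ level seen by the self-activation and
Phox2b-repression terms; it equals ``T`` for an isolated cell and a
self/neighbour average on a lattice. The linear −T decay always uses the
cell's own ``T``. The self-activation weight enters once, as the convex
combination coefficient ω_TT; the inner Hill is unweighted (applying the
(1−ω)+ω·H form a second time would both double-count the weight and, with
the tabulated parameters, destroy the bistability that defines the
hysteretic variant).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Union

import numpy as np

__all__ = [
    "NetworkWeights",
    "HillThresholds",
    "KineticRates",
    "NoiseSettings",
    "SystemState",
    "ModelConfig",
    "hill_pos",
    "hill_neg",
    "weighted_hill_pos",
    "weighted_hill_neg",
    "rhs",
    "rhs_arrays",
    "quasi_steady_P",
]

ArrayLike = Union[float, np.ndarray]


def _check_xh(x: ArrayLike, h: float) -> None:
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)) or np.any(x < 0):
        raise ValueError("concentration x must be finite and non-negative")
    if h is None or not np.isfinite(h) or h <= 0:
        raise ValueError("Hill threshold h must be finite and positive")


def hill_pos(x: ArrayLike, h: float, n: int = 2) -> ArrayLike:
    """Activating Hill function xⁿ/(hⁿ + xⁿ); 0 at x=0, →1 as x→∞."""
    _check_xh(x, h)
    xn = np.asarray(x, dtype=float) ** n
    return xn / (h**n + xn)


def hill_neg(x: ArrayLike, h: float, n: int = 2) -> ArrayLike:
    """Repressing Hill function hⁿ/(hⁿ + xⁿ); complement of :func:`hill_pos`."""
    _check_xh(x, h)
    hn = float(h) ** n
    return hn / (hn + np.asarray(x, dtype=float) ** n)


def _check_omega(omega: float) -> None:
    if not np.isfinite(omega) or omega < 0 or omega > 1:
        raise ValueError(f"link weight omega must lie in [0, 1], got {omega!r}")


def weighted_hill_pos(x: ArrayLike, h: Optional[float], omega: float, n: int = 2) -> ArrayLike:
    """(1−ω) + ω·H⁺(x,h).  ω=0 gives identically 1 and never reads h."""
    _check_omega(omega)
    if omega == 0:
        return np.ones_like(np.asarray(x, dtype=float)) if np.ndim(x) else 1.0
    return (1.0 - omega) + omega * hill_pos(x, h, n)


def weighted_hill_neg(x: ArrayLike, h: Optional[float], omega: float, n: int = 2) -> ArrayLike:
    """(1−ω) + ω·H⁻(x,h).  ω=0 gives identically 1 and never reads h."""
    _check_omega(omega)
    if omega == 0:
        return np.ones_like(np.asarray(x, dtype=float)) if np.ndim(x) else 1.0
    return (1.0 - omega) + omega * hill_neg(x, h, n)


@dataclass(frozen=True)
class NetworkWeights:
    """Dimensionless link weights ω, each in [0, 1]; 0 removes the link."""

    omega_AT: float = 0.0
    omega_RT: float = 0.0
    omega_TT: float = 0.0
    omega_AP: float = 0.0
    omega_TP: float = 0.0

    def __post_init__(self) -> None:
        for name in ("omega_AT", "omega_RT", "omega_TT", "omega_AP", "omega_TP"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0 or v > 1:
                raise ValueError(f"{name} must lie in [0, 1], got {v!r}")


@dataclass(frozen=True)
class HillThresholds:
    """Half-activation constants h; may be None for links whose weight is 0."""

    h_AT: Optional[float] = None
    h_RT: Optional[float] = None
    h_TT: Optional[float] = None
    h_AP: Optional[float] = None
    h_TP: Optional[float] = None


@dataclass(frozen=True)
class KineticRates:
    """Decay rates of GliA/GliR and production/decay scales of Tgfβ/Phox2b.

    Units are 1/day. ``lambda_A``/``lambda_R`` may be zero (a clamped,
    non-decaying Gli pool, used by the Gli1-ON mutant); ``v_T``/``v_P``
    must be positive.
    """

    lambda_A: float = 0.86
    lambda_R: float = 0.86
    v_T: float = 50.0
    v_P: float = 90.0

    def __post_init__(self) -> None:
        for name in ("lambda_A", "lambda_R"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v!r}")
        for name in ("v_T", "v_P"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be finite and > 0, got {v!r}")


@dataclass(frozen=True)
class NoiseSettings:
    """Kinetic (multiplicative) noise ε ≥ 0 and readout threshold noise η > 0.

    ``correlated_AR`` selects identical (rather than independent) Wiener
    increments for the A and R equations.
    """

    epsilon: float = 0.0
    eta: float = 1.0
    correlated_AR: bool = False

    def __post_init__(self) -> None:
        if not np.isfinite(self.epsilon) or self.epsilon < 0:
            raise ValueError(f"epsilon must be >= 0, got {self.epsilon!r}")
        if not np.isfinite(self.eta) or self.eta <= 0:
            raise ValueError(f"eta must be > 0, got {self.eta!r}")


@dataclass(frozen=True)
class SystemState:
    """One point in state space: (A, R, T, P), all non-negative."""

    A: float = 1.0
    R: float = 1.0
    T: float = 0.0
    P: float = 1.0

    def __post_init__(self) -> None:
        for name in ("A", "R", "T", "P"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"state component {name} must be finite and >= 0")

    def as_array(self) -> np.ndarray:
        return np.array([self.A, self.R, self.T, self.P], dtype=float)

    @classmethod
    def from_array(cls, arr: np.ndarray) -> "SystemState":
        return cls(A=float(arr[0]), R=float(arr[1]), T=float(arr[2]), P=float(arr[3]))


VARIABLES = ("A", "R", "T", "P")


@dataclass(frozen=True)
class ModelConfig:
    """Full parameterisation of one network variant."""

    weights: NetworkWeights = field(default_factory=NetworkWeights)
    thresholds: HillThresholds = field(default_factory=HillThresholds)
    rates: KineticRates = field(default_factory=KineticRates)
    noise: NoiseSettings = field(default_factory=NoiseSettings)
    initial_state: SystemState = field(default_factory=SystemState)
    hill_coefficient: int = 2
    t_end: float = 6.0
    dt: float = 1e-3

    def __post_init__(self) -> None:
        if self.hill_coefficient < 1:
            raise ValueError("hill_coefficient must be a positive integer")
        if not (np.isfinite(self.dt) and self.dt > 0):
            raise ValueError("dt must be > 0")
        if not (np.isfinite(self.t_end) and self.t_end > 0):
            raise ValueError("t_end must be > 0")
        # each active link needs a usable threshold
        pairs = [
            ("omega_AT", "h_AT"),
            ("omega_RT", "h_RT"),
            ("omega_TT", "h_TT"),
            ("omega_AP", "h_AP"),
            ("omega_TP", "h_TP"),
        ]
        for wname, hname in pairs:
            w = getattr(self.weights, wname)
            h = getattr(self.thresholds, hname)
            if w > 0 and (h is None or not np.isfinite(h) or h <= 0):
                raise ValueError(
                    f"{hname} must be finite and > 0 because {wname} = {w}"
                )

    def with_overrides(self, **kwargs) -> "ModelConfig":
        """Return a copy with replaced top-level fields (dataclass replace)."""
        return replace(self, **kwargs)


def quasi_steady_P(A0: float, config_weights: NetworkWeights,
                   config_thresholds: HillThresholds, n: int = 2) -> float:
    """Quasi-steady Phox2b at T = 0: Hʷ⁺(A0,h_AP,ω_AP)·Hʷ⁻(0,h_TP,ω_TP)."""
    return float(
        weighted_hill_pos(A0, config_thresholds.h_AP, config_weights.omega_AP, n)
        * weighted_hill_neg(0.0, config_thresholds.h_TP, config_weights.omega_TP, n)
    )


def rhs_arrays(A, R, T, P, config: ModelConfig, T_eff=None):
    """Vectorised time derivatives (dA, dR, dT, dP).

    ``T_eff`` is the Tgfβ input to the self-activation and Phox2b-repression
    terms; defaults to ``T``. All arguments broadcast as numpy arrays.
    """
    if T_eff is None:
        T_eff = T
    w, h, r, n = config.weights, config.thresholds, config.rates, config.hill_coefficient
    dA = -r.lambda_A * A
    dR = -r.lambda_R * R
    prod_T = (1.0 - w.omega_TT) * (
        weighted_hill_pos(A, h.h_AT, w.omega_AT, n)
        * weighted_hill_neg(R, h.h_RT, w.omega_RT, n)
    )
    if w.omega_TT > 0:
        prod_T = prod_T + w.omega_TT * hill_pos(T_eff, h.h_TT, n)
    dT = r.v_T * (prod_T - T)
    dP = r.v_P * (
        weighted_hill_pos(A, h.h_AP, w.omega_AP, n)
        * weighted_hill_neg(T_eff, h.h_TP, w.omega_TP, n)
        - P
    )
    return dA, dR, dT, dP


def rhs(state: SystemState, config: ModelConfig,
        T_eff: Optional[float] = None) -> SystemState:
    """Time derivative of a single state (returned as a SystemState-shaped tuple)."""
    arr = state.as_array()
    if not np.all(np.isfinite(arr)):
        raise ValueError("non-finite state components")
    dA, dR, dT, dP = rhs_arrays(arr[0], arr[1], arr[2], arr[3], config, T_eff)
    return np.array([dA, dR, dT, dP], dtype=float)
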