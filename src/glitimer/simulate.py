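"""Deterministic and stochastic integration of the timer network.

Deterministic trajectories use a fixed-step classical Runge–Kutta (RK4)
scheme; stochastic paths use Euler–Maruyama with scalar multiplicative
noise, dx = f dt + ε·x·dW applied to every variable. With
``correlated_AR`` the A and R equations receive identical Wiener
increments, otherwise independent ones. Concentrations are clipped at 0
after each stochastic step (0 is absorbing for the exact multiplicative
process).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .model import ModelConfig, SystemState, VARIABLES, rhs_arrays

__all__ = [
    "Trajectory",
    "EnsembleSummary",
    "IntegrationError",
    "integrate_ode",
    "integrate_sde",
    "run_ensemble",
    "simulate_paths",
]


class IntegrationError(RuntimeError):
    """Raised when a state component becomes non-finite during integration."""


@dataclass
class Trajectory:
    """A single time-indexed path of the four-variable system."""

    times: np.ndarray
    states: np.ndarray  # shape (n_times, 4), columns A, R, T, P
    config: Optional[ModelConfig] = None
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.states = np.asarray(self.states, dtype=float)
        if self.times.ndim != 1 or self.states.shape != (self.times.size, 4):
            raise ValueError("states must have shape (len(times), 4)")
        if self.times[0] != 0.0 or np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing and start at 0")

    @property
    def A(self) -> np.ndarray:
        return self.states[:, 0]

    @property
    def R(self) -> np.ndarray:
        return self.states[:, 1]

    @property
    def T(self) -> np.ndarray:
        return self.states[:, 2]

    @property
    def P(self) -> np.ndarray:
        return self.states[:, 3]

    def to_frame(self) -> pd.DataFrame:
        """Tidy long-format frame with columns time, variable, value."""
        frames = [
            pd.DataFrame({"time": self.times, "variable": v, "value": self.states[:, i]})
            for i, v in enumerate(VARIABLES)
        ]
        return pd.concat(frames, ignore_index=True)


@dataclass
class EnsembleSummary:
    """Median and quantile envelope of an ensemble of stochastic paths.

    ``paths`` optionally retains the full replicate array
    (n_replicates, n_times, 4); the readout module uses it to average
    per-replicate differentiation likelihoods.
    """

    times: np.ndarray
    median: np.ndarray  # (n_times, 4)
    lower: np.ndarray
    upper: np.ndarray
    n_replicates: int
    quantiles: tuple = (0.05, 0.95)
    config: Optional[ModelConfig] = None
    seed: Optional[int] = None
    paths: Optional[np.ndarray] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if np.any(self.lower > self.median) or np.any(self.median > self.upper):
            raise ValueError("quantile envelope must satisfy lower <= median <= upper")

    def to_frame(self) -> pd.DataFrame:
        frames = []
        for i, v in enumerate(VARIABLES):
            for qname, arr in (("median", self.median), ("lower", self.lower), ("upper", self.upper)):
                frames.append(
                    pd.DataFrame(
                        {"time": self.times, "variable": v, "quantile": qname, "value": arr[:, i]}
                    )
                )
        return pd.concat(frames, ignore_index=True)


def _check_finite(arr: np.ndarray, t: float) -> None:
    if np.all(np.isfinite(arr)):
        return
    bad = np.where(~np.isfinite(arr))
    var = VARIABLES[int(bad[-1][0])] if arr.ndim else "state"
    raise IntegrationError(
        f"non-finite value in variable {var} at t = {t:.6g}; reduce dt"
    )


def _time_grid(config: ModelConfig, record_every: int):
    n_steps = int(round(config.t_end / config.dt))
    rec_idx = np.arange(0, n_steps + 1, record_every)
    if rec_idx[-1] != n_steps:
        rec_idx = np.append(rec_idx, n_steps)
    return n_steps, rec_idx


def integrate_ode(config: ModelConfig, record_every: int = 1) -> Trajectory:
    """Deterministic trajectory (kinetic noise ignored), fixed-step RK4."""
    dt = config.dt
    n_steps, rec_idx = _time_grid(config, record_every)
    y = config.initial_state.as_array()
    out = np.empty((rec_idx.size, 4))
    out[0] = y
    rec_pos = 1
    for step in range(n_steps):
        k1 = np.array(rhs_arrays(*y, config))
        y2 = np.clip(y + 0.5 * dt * k1, 0.0, None)
        k2 = np.array(rhs_arrays(*y2, config))
        y3 = np.clip(y + 0.5 * dt * k2, 0.0, None)
        k3 = np.array(rhs_arrays(*y3, config))
        y4 = np.clip(y + dt * k3, 0.0, None)
        k4 = np.array(rhs_arrays(*y4, config))
        y = y + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        _check_finite(y, (step + 1) * dt)
        if rec_pos < rec_idx.size and step + 1 == rec_idx[rec_pos]:
            out[rec_pos] = y
            rec_pos += 1
    return Trajectory(times=rec_idx * dt, states=out, config=config, seed=None)


def simulate_paths(
    config: ModelConfig,
    n_paths: int,
    seed: int,
    record_every: int = 10,
    initial: Optional[np.ndarray] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Euler–Maruyama ensemble, vectorised over replicates.

    Returns ``(times, paths)`` with ``paths`` of shape
    (n_paths, n_recorded, 4). Replicate r consumes column r of the noise
    stream seeded by ``seed``, so the whole ensemble is reproducible from
    the single base seed.
    """
    if n_paths < 1:
        raise ValueError("n_paths must be >= 1")
    dt = config.dt
    eps = config.noise.epsilon
    corr = config.noise.correlated_AR
    n_steps, rec_idx = _time_grid(config, record_every)
    rng = np.random.default_rng(seed)
    sqdt = np.sqrt(dt)

    y = np.tile(
        config.initial_state.as_array() if initial is None else np.asarray(initial, float),
        (n_paths, 1),
    )
    out = np.empty((n_paths, rec_idx.size, 4))
    out[:, 0, :] = y
    rec_pos = 1
    def drift(state):
        dA, dR, dT, dP = rhs_arrays(state[:, 0], state[:, 1], state[:, 2], state[:, 3], config)
        return np.stack([dA, dR, dT, dP], axis=1)

    for step in range(n_steps):
        if eps > 0:
            z = rng.standard_normal((n_paths, 4))
            if corr:
                z[:, 1] = z[:, 0]
            y = y + dt * drift(y) + eps * y * (sqdt * z)
            np.clip(y, 0.0, None, out=y)
        else:
            # degenerate SDE: fall back to the deterministic RK4 step so the
            # ε=0 ensemble coincides with integrate_ode to round-off
            k1 = drift(y)
            k2 = drift(np.clip(y + 0.5 * dt * k1, 0.0, None))
            k3 = drift(np.clip(y + 0.5 * dt * k2, 0.0, None))
            k4 = drift(np.clip(y + dt * k3, 0.0, None))
            y = y + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        if rec_pos < rec_idx.size and step + 1 == rec_idx[rec_pos]:
            _check_finite(y, (step + 1) * dt)
            out[:, rec_pos, :] = y
            rec_pos += 1
    return rec_idx * dt, out


def integrate_sde(config: ModelConfig, seed: int, record_every: int = 10) -> Trajectory:
    """Single Euler–Maruyama path; with ε = 0 it reproduces the drift-only
    Euler path (and converges to :func:`integrate_ode` as dt → 0)."""
    times, paths = simulate_paths(config, 1, seed, record_every=record_every)
    return Trajectory(times=times, states=paths[0], config=config, seed=seed)


def run_ensemble(
    config: ModelConfig,
    n_replicates: int,
    base_seed: int,
    record_every: int = 10,
    quantiles: tuple = (0.05, 0.95),
    keep_paths: bool = True,
) -> EnsembleSummary:
    """Ensemble of replicate SDE paths with per-time-point quantile envelope."""
    times, paths = simulate_paths(config, n_replicates, base_seed, record_every)
    lo = np.quantile(paths, quantiles[0], axis=0)
    hi = np.quantile(paths, quantiles[1], axis=0)
    med = np.median(paths, axis=0)
    return EnsembleSummary(
        times=times,
        median=med,
        lower=lo,
        upper=hi,
        n_replicates=n_replicates,
        quantiles=quantiles,
        config=config,
        seed=base_seed,
        paths=paths if keep_paths else None,
    )
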