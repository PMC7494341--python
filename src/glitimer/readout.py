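"""Gamma-CDF threshold readout of Phox2b and transition statistics.

A cell's likelihood of motor-neuron (MN) differentiation given its Phox2b
level P is the CDF of a gamma-distributed threshold with shape k = 10/η and
scale θ = 0.04·η, so the threshold mean k·θ = 0.4 is independent of the
noise level η while the variance k·θ² = 0.016·η grows linearly with it.

The population transition period Δt is the time for the population MN
likelihood to fall from 0.95 to 0.05; the switch time is the 0.5 crossing.
For ensembles the population likelihood is the across-replicate mean of the
per-replicate likelihoods (the average is taken after the nonlinearity, so
cell-to-cell variability broadens the population curve). Applying the
readout to the median path instead is exposed for comparison via
``method="median"``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Union

import numpy as np
import pandas as pd
from scipy.special import gammainc

from .simulate import EnsembleSummary, Trajectory

__all__ = [
    "ReadoutModel",
    "LikelihoodCurve",
    "SwitchStatistics",
    "mn_likelihood",
    "likelihood_path",
    "switch_statistics",
]


@dataclass(frozen=True)
class ReadoutModel:
    """Threshold-noise readout; η > 0 is the threshold noise level."""

    eta: float = 1.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.eta) or self.eta <= 0:
            raise ValueError(f"eta must be > 0, got {self.eta!r}")

    @property
    def shape(self) -> float:
        return 10.0 / self.eta

    @property
    def scale(self) -> float:
        return 0.04 * self.eta

    @property
    def mean(self) -> float:
        return self.shape * self.scale

    @property
    def variance(self) -> float:
        return self.shape * self.scale**2


def mn_likelihood(P, readout: ReadoutModel):
    """GammaCDF(P; k, θ) via the regularized lower incomplete gamma function."""
    P = np.asarray(P, dtype=float)
    if np.any(P < 0) or not np.all(np.isfinite(P)):
        raise ValueError("Phox2b concentration must be finite and >= 0")
    out = gammainc(readout.shape, P / readout.scale)
    return float(out) if out.ndim == 0 else out


@dataclass
class LikelihoodCurve:
    """Time-indexed MN-differentiation likelihood."""

    times: np.ndarray
    values: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.times, "likelihood": self.values})


def likelihood_path(
    obj: Union[Trajectory, EnsembleSummary],
    readout: ReadoutModel,
    method: str = "replicates",
) -> LikelihoodCurve:
    """Likelihood curve of a single path or the population curve of an ensemble.

    For an :class:`EnsembleSummary` with retained paths, the per-replicate
    likelihood is computed first and then averaged across replicates at each
    time point (``method="replicates"``, the default). ``method="median"``
    instead applies the readout to the median P path.
    """
    if isinstance(obj, Trajectory):
        return LikelihoodCurve(obj.times, mn_likelihood(obj.P, readout))
    if method == "replicates":
        if obj.paths is None:
            raise ValueError(
                "ensemble was summarised without keep_paths=True; "
                "re-run with keep_paths or use method='median'"
            )
        per_rep = mn_likelihood(obj.paths[:, :, 3], readout)
        return LikelihoodCurve(obj.times, per_rep.mean(axis=0))
    if method == "median":
        return LikelihoodCurve(obj.times, mn_likelihood(obj.median[:, 3], readout))
    raise ValueError(f"unknown method {method!r}")


@dataclass
class SwitchStatistics:
    """Crossing times of the MN likelihood: 0.95, 0.5 and 0.05 levels.

    Absent crossings are None, with an explanatory flag: ``no_mn_phase`` if
    the curve never exceeds 0.95, ``no_switch`` if it never falls below 0.05
    (the expected output for the Gli1-ON:Tgfbr1-KO mutant).
    """

    t_95: Optional[float]
    t_05: Optional[float]
    t_switch: Optional[float]
    delta_t: Optional[float]
    flags: List[str]


def _downward_crossings(t: np.ndarray, y: np.ndarray, level: float) -> np.ndarray:
    """Linearly interpolated times of all downward crossings of ``level``."""
    above = y >= level
    idx = np.where(above[:-1] & ~above[1:])[0]
    if idx.size == 0:
        return np.empty(0)
    frac = (y[idx] - level) / (y[idx] - y[idx + 1])
    return t[idx] + frac * (t[idx + 1] - t[idx])


def switch_statistics(
    curve: LikelihoodCurve, upper: float = 0.95, lower: float = 0.05
) -> SwitchStatistics:
    """Transition statistics of a likelihood curve.

    If noise makes the curve non-monotone, the last downward crossing of the
    upper level and the first downward crossing of the lower level are used
    (the widest, most conservative transition interval).
    """
    t, y = np.asarray(curve.times), np.asarray(curve.values)
    flags: List[str] = []
    cross_hi = _downward_crossings(t, y, upper)
    cross_lo = _downward_crossings(t, y, lower)
    cross_mid = _downward_crossings(t, y, 0.5)

    t_95 = float(cross_hi[-1]) if cross_hi.size else None
    if t_95 is None:
        flags.append("no_mn_phase" if not np.any(y >= upper) else "no_upper_crossing")
    t_05 = float(cross_lo[0]) if cross_lo.size else None
    if t_05 is None:
        flags.append("no_switch")
    t_switch = float(cross_mid[-1]) if cross_mid.size else None
    delta_t = t_05 - t_95 if (t_95 is not None and t_05 is not None) else None
    return SwitchStatistics(t_95=t_95, t_05=t_05, t_switch=t_switch,
                            delta_t=delta_t, flags=flags)
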