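"""Flat YAML serialisation of :class:`~glitimer.model.ModelConfig` and run manifests.

Config files are flat key-value YAML with exactly the keys below; unknown
keys are rejected so typos cannot silently fall back to defaults. Threshold
keys paired with a zero weight may be omitted or null.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Dict, List, Optional

import yaml

from . import __version__
from .model import (
    HillThresholds,
    KineticRates,
    ModelConfig,
    NetworkWeights,
    NoiseSettings,
    SystemState,
)

__all__ = ["CONFIG_KEYS", "load_config", "save_config", "config_to_dict",
           "bundled_config_path", "RunManifest", "write_manifest"]

_WEIGHT_KEYS = ("omega_AT", "omega_RT", "omega_TT", "omega_AP", "omega_TP")
_THRESHOLD_KEYS = ("h_AT", "h_RT", "h_TT", "h_AP", "h_TP")
_RATE_KEYS = ("lambda_A", "lambda_R", "v_T", "v_P")
_NOISE_KEYS = ("epsilon", "eta", "correlated_AR")
_STATE_KEYS = ("A0", "R0", "T0", "P0")
_TIME_KEYS = ("t_end", "dt")

CONFIG_KEYS = (
    _WEIGHT_KEYS + _THRESHOLD_KEYS + _RATE_KEYS + _NOISE_KEYS
    + _STATE_KEYS + _TIME_KEYS + ("hill_coefficient",)
)

_OPTIONAL_KEYS = set(_THRESHOLD_KEYS) | {"correlated_AR", "hill_coefficient"}


def config_to_dict(config: ModelConfig) -> Dict[str, object]:
    d: Dict[str, object] = {}
    for k in _WEIGHT_KEYS:
        d[k] = float(getattr(config.weights, k))
    for k in _THRESHOLD_KEYS:
        v = getattr(config.thresholds, k)
        d[k] = None if v is None else float(v)
    for k in _RATE_KEYS:
        d[k] = float(getattr(config.rates, k))
    d["epsilon"] = float(config.noise.epsilon)
    d["eta"] = float(config.noise.eta)
    d["correlated_AR"] = bool(config.noise.correlated_AR)
    s = config.initial_state
    d.update(A0=float(s.A), R0=float(s.R), T0=float(s.T), P0=float(s.P))
    d["t_end"] = float(config.t_end)
    d["dt"] = float(config.dt)
    d["hill_coefficient"] = int(config.hill_coefficient)
    return d


def _config_from_dict(d: Dict[str, object], source: str) -> ModelConfig:
    unknown = sorted(set(d) - set(CONFIG_KEYS))
    if unknown:
        raise ValueError(f"{source}: unknown config keys: {', '.join(unknown)}")
    missing = sorted(k for k in CONFIG_KEYS
                     if k not in d and k not in _OPTIONAL_KEYS)
    if missing:
        raise ValueError(f"{source}: missing config keys: {', '.join(missing)}")
    try:
        weights = NetworkWeights(**{k: float(d[k]) for k in _WEIGHT_KEYS})
        thresholds = HillThresholds(**{
            k: (None if d.get(k) is None else float(d[k])) for k in _THRESHOLD_KEYS
        })
        rates = KineticRates(**{k: float(d[k]) for k in _RATE_KEYS})
        noise = NoiseSettings(epsilon=float(d["epsilon"]), eta=float(d["eta"]),
                              correlated_AR=bool(d.get("correlated_AR", False)))
        state = SystemState(A=float(d["A0"]), R=float(d["R0"]),
                            T=float(d["T0"]), P=float(d["P0"]))
        return ModelConfig(
            weights=weights, thresholds=thresholds, rates=rates, noise=noise,
            initial_state=state, hill_coefficient=int(d.get("hill_coefficient", 2)),
            t_end=float(d["t_end"]), dt=float(d["dt"]),
        )
    except ValueError as exc:
        raise ValueError(f"{source}: {exc}") from exc


def load_config(path) -> ModelConfig:
    """Load and validate a flat YAML model configuration."""
    path = Path(path)
    with open(path) as fh:
        d = yaml.safe_load(fh)
    if not isinstance(d, dict):
        raise ValueError(f"{path}: config file must contain a mapping")
    return _config_from_dict(d, str(path))


def save_config(config: ModelConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=False)


def bundled_config_path(name: str) -> Path:
    """Path of a bundled canonical config (one per network-variant row)."""
    from importlib.resources import files

    p = files("glitimer").joinpath("configs", f"{name}.yaml")
    if not p.is_file():
        available = sorted(q.stem for q in (files("glitimer") / "configs").iterdir())
        raise ValueError(f"no bundled config {name!r}; available: {', '.join(available)}")
    return Path(str(p))


@dataclass
class RunManifest:
    """Machine-readable record of one CLI run: command, config, seeds and
    checksums of every output file, enabling byte-level reproduction of
    deterministic runs."""

    command: str
    config: Dict[str, object]
    seeds: List[int]
    outputs: Dict[str, str] = field(default_factory=dict)  # path -> sha256
    package_version: str = __version__
    timestamp: str = ""

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, default=str)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(path, command: str, config: Optional[ModelConfig],
                   seeds: List[int], output_files: List[Path]) -> RunManifest:
    manifest = RunManifest(
        command=command,
        config=config_to_dict(config) if config is not None else {},
        seeds=list(seeds),
        outputs={str(p): _sha256(Path(p)) for p in output_files if Path(p).is_file()},
        timestamp=datetime.now(timezone.utc).isoformat(),
    )
    Path(path).write_text(manifest.to_json() + "\n")
    return manifest
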