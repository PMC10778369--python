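"""Run configuration: profiles, YAML round-trip, and validation.

Two profiles are provided: ``desk`` (CPU-scale defaults used by the test
suite) and ``paper`` (the published training scale: 1024-px crops,
4096-px context windows, lr 0.001, momentum 0.9, weight decay 0.0005,
300 epochs).
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass, field

import yaml

from .ki67 import DetectionParams
from .losses import LossWeights
from .multiscale import Stage2Config
from .network import NetworkConfig
from .stage1 import Stage1Config

__all__ = ["SynthConfig", "RunConfig", "load_config", "save_config",
           "PROFILES"]


@dataclass
class SynthConfig:
    size_px: int = 256
    n_tiles: int = 16
    stains: tuple[str, ...] = ("ER", "PR", "HER2", "Ki67")
    scenarios: tuple[str, ...] = ("normal", "dcis", "invasive", "mixed")
    positivity_range: tuple[float, float] = (0.1, 0.6)
    confounder_prob: float = 0.5
    wsi_size: int = 1280


@dataclass
class InferenceConfig:
    context_side: int = 512
    sat_threshold: float = 0.05


@dataclass
class RunConfig:
    profile: str = "desk"
    seed: int = 0
    out_dir: str = "runs"
    synth: SynthConfig = field(default_factory=SynthConfig)
    network: NetworkConfig = field(default_factory=NetworkConfig)
    losses: LossWeights = field(default_factory=LossWeights)
    stage1: Stage1Config = field(default_factory=Stage1Config)
    stage2: Stage2Config = field(default_factory=Stage2Config)
    inference: InferenceConfig = field(default_factory=InferenceConfig)
    ki67: DetectionParams = field(default_factory=DetectionParams)


PROFILES: dict[str, dict] = {
    # CPU-scale defaults; tuned so the full pipeline runs on one core
    "desk": {
        "network": {"size_preset": "tiny"},
        "stage1": {"crop": 128, "epochs": 20, "lr": 0.02},
        "inference": {"context_side": 512},
    },
    # published training scale
    "paper": {
        "network": {"size_preset": "M"},
        "stage1": {"crop": 1024, "epochs": 300, "lr": 0.001,
                   "momentum": 0.9, "weight_decay": 0.0005},
        "inference": {"context_side": 4096},
    },
}


def _build(cls, values: dict, path: str):
    fields = {f.name: f for f in dataclasses.fields(cls)}
    kwargs = {}
    for key, val in values.items():
        if key not in fields:
            raise ValueError(f"unknown config field {path}.{key}")
        ftype = fields[key].type
        if isinstance(val, dict) and key in _SECTION_TYPES:
            val = _build(_SECTION_TYPES[key], val, f"{path}.{key}")
        elif isinstance(val, list):
            val = tuple(val)
        kwargs[key] = val
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"invalid configuration at {path}: {exc}") from exc


_SECTION_TYPES = {
    "synth": SynthConfig,
    "network": NetworkConfig,
    "losses": LossWeights,
    "stage1": Stage1Config,
    "stage2": Stage2Config,
    "inference": InferenceConfig,
    "ki67": DetectionParams,
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for key, val in override.items():
        if isinstance(val, dict) and isinstance(out.get(key), dict):
            out[key] = _merge(out[key], val)
        else:
            out[key] = val
    return out


def load_config(path: str | None = None, profile: str | None = None,
                overrides: dict | None = None) -> RunConfig:
    """Resolve profile defaults < YAML file < explicit overrides."""
    raw: dict = {}
    if path:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
    profile = profile or raw.get("profile", "desk")
    if profile not in PROFILES:
        raise ValueError(f"unknown profile {profile!r}")
    merged = _merge(PROFILES[profile], raw)
    if overrides:
        merged = _merge(merged, overrides)
    merged["profile"] = profile
    # stage1 carries its own nested network config; keep them in sync
    net_section = merged.get("network", {})
    merged.setdefault("stage1", {})
    if isinstance(merged["stage1"], dict):
        merged["stage1"].setdefault("network", net_section)
    return _build(RunConfig, merged, "config")


def save_config(cfg: RunConfig, path: str) -> None:
    os.makedirs(os.path.dirname(path) or ".", exist_ok=True)

    def plain(obj):
        if dataclasses.is_dataclass(obj):
            return {k: plain(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, tuple):
            return [plain(v) for v in obj]
        if isinstance(obj, dict):
            return {k: plain(v) for k, v in obj.items()}
        return obj

    with open(path, "w") as fh:
        yaml.safe_dump(plain(cfg), fh, sort_keys=False)
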