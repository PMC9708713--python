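"""YAML configuration: one file with a section per pipeline stage."""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path

import yaml

from .anatomy import AnatomyConfig
from .degradation import DegradationConfig
from .network import NetworkSpec
from .phantom import DEFAULT_ACTIVITY_DISTS
from .training import TilingConfig, TrainConfig


def default_config() -> dict:
    """Full default configuration as a plain nested dict."""
    return {
        "anatomy": asdict(AnatomyConfig()),
        "activity": {
            "distributions": {k: list(v) for k, v in DEFAULT_ACTIVITY_DISTS.items()},
        },
        "degradation": asdict(DegradationConfig()),
        "network": asdict(NetworkSpec()),
        "training": asdict(TrainConfig()),
        "tiling": asdict(TilingConfig()),
        "evaluation": {"erosion_radius_vox": 6, "psnr_denominator": "rmse"},
    }


def _tuplify(d):
    if isinstance(d, list):
        return tuple(_tuplify(x) for x in d)
    if isinstance(d, dict):
        return {k: _tuplify(v) for k, v in d.items()}
    return d


def load_config(path) -> dict:
    """Load a YAML config, filling unset sections/keys with defaults."""
    cfg = default_config()
    user = yaml.safe_load(Path(path).read_text()) or {}
    for section, values in user.items():
        if section in cfg and isinstance(cfg[section], dict) and isinstance(values, dict):
            cfg[section].update(values)
        else:
            cfg[section] = values
    return cfg


def save_config(cfg: dict, path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg, sort_keys=False))


def anatomy_config(cfg: dict) -> AnatomyConfig:
    return AnatomyConfig(**_tuplify(cfg["anatomy"]))


def degradation_config(cfg: dict) -> DegradationConfig:
    return DegradationConfig(**_tuplify(cfg["degradation"]))


def network_spec(cfg: dict) -> NetworkSpec:
    return NetworkSpec(**_tuplify(cfg["network"]))


def train_config(cfg: dict) -> TrainConfig:
    return TrainConfig(**_tuplify(cfg["training"]))


def tiling_config(cfg: dict) -> TilingConfig:
    return TilingConfig(**_tuplify(cfg["tiling"]))


def activity_distributions(cfg: dict) -> dict[str, tuple[float, float]]:
    return {k: tuple(v) for k, v in cfg["activity"]["distributions"].items()}
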