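"""YAML run configuration: parsing, validation and replayable echoes.

One YAML file carries subcommand-specific sections (``cohort``, ``model``
with nested ``backbone``/``pooling``, ``train``, ``augmentation``,
``seeds``).  Unknown keys are rejected with their names so typos cannot
silently fall back to defaults, and every run writes a resolved config echo
sufficient to replay it.
"""

from __future__ import annotations

from dataclasses import fields
from pathlib import Path

import yaml

from .backbone import BackboneConfig
from .cohort import CohortSpec
from .model import ModelConfig
from .pipeline import AugmentationSpec
from .pooling import PoolingSpec
from .training import TrainConfig

__all__ = [
    "ConfigError",
    "load_config",
    "model_config_from",
    "train_config_from",
    "cohort_spec_from",
    "augmentation_spec_from",
    "write_echo",
]

TOP_LEVEL_KEYS = {"cohort", "model", "train", "augmentation", "seeds", "paths"}


class ConfigError(ValueError):
    pass


def _check_keys(d: dict, allowed, where: str):
    unknown = sorted(set(d) - set(allowed))
    if unknown:
        raise ConfigError(f"unknown config key(s) under {where}: {unknown}")


def _build(cls, d: dict, where: str, **convert):
    d = dict(d)
    _check_keys(d, [f.name for f in fields(cls)], where)
    for key, fn in convert.items():
        if key in d:
            d[key] = fn(d[key])
    try:
        return cls(**d)
    except (TypeError, ValueError) as e:
        raise ConfigError(f"invalid {where} section: {e}") from e


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ConfigError(f"config {path} must be a YAML mapping")
    _check_keys(cfg, TOP_LEVEL_KEYS, "the top level")
    return cfg


def _pooling_from(d: dict, kind: str, where: str) -> PoolingSpec:
    d = dict(d)
    _check_keys(d, {"levels", "operator"}, where)
    levels = tuple(tuple(l) for l in d.get("levels", ()))
    default = PoolingSpec.spp_default() if kind == "SPP" else PoolingSpec.msp_default()
    return PoolingSpec(
        kind,
        levels or default.levels,
        d.get("operator", default.operator),
    )


def model_config_from(cfg: dict) -> ModelConfig:
    section = dict(cfg.get("model", {}))
    _check_keys(
        section,
        {"backbone", "pooling", "fc_sizes", "n_classes", "dropout_drop_p", "tie_fe_weights"},
        "model",
    )
    backbone = _build(
        BackboneConfig,
        section.get("backbone", {}),
        "model.backbone",
        convs_per_block=tuple,
        channels=tuple,
    )
    pooling = dict(section.get("pooling", {}))
    _check_keys(pooling, {"transverse", "longitudinal"}, "model.pooling")
    kwargs = {}
    if "fc_sizes" in section:
        kwargs["fc_sizes"] = tuple(section["fc_sizes"])
    for key in ("n_classes", "dropout_drop_p", "tie_fe_weights"):
        if key in section:
            kwargs[key] = section[key]
    return ModelConfig(
        backbone=backbone,
        pooling_T=_pooling_from(pooling.get("transverse", {}), "SPP", "model.pooling.transverse"),
        pooling_L=_pooling_from(pooling.get("longitudinal", {}), "MSP", "model.pooling.longitudinal"),
        **kwargs,
    )


def train_config_from(cfg: dict) -> TrainConfig:
    return _build(TrainConfig, cfg.get("train", {}), "train")


def cohort_spec_from(cfg: dict) -> CohortSpec:
    return _build(
        CohortSpec,
        cfg.get("cohort", {}),
        "cohort",
        transverse_size_range=tuple,
        longitudinal_height_range=tuple,
        longitudinal_aspect_range=tuple,
    )


def augmentation_spec_from(cfg: dict) -> AugmentationSpec:
    return _build(
        AugmentationSpec,
        cfg.get("augmentation", {}),
        "augmentation",
        scale_factors=tuple,
        flips=tuple,
    )


def write_echo(cfg: dict, out_dir) -> Path:
    """Persist the resolved configuration so the run can be replayed."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    echo = out_dir / "config_echo.yaml"
    with open(echo, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
    return echo
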