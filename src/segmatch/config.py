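"""YAML run configuration with profiles and strict schema validation.

A run config resolves to fully-specified dataclasses; unknown keys are
rejected by name. Two profiles ship with the package: ``desk`` (small
model, few epochs, K=3 — used by the whole test suite) and ``paper``
(full-scale settings: depth-6 model, 1000 epochs, batch 64, K=25).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any, Dict, Optional

import yaml

from segmatch.adversarial import AdversarialConfig
from segmatch.backbone import ModelConfig
from segmatch.errors import ConfigurationError
from segmatch.losses import LossConfig
from segmatch.metrics import scaled_tolerance
from segmatch.synthetic import SceneConfig
from segmatch.trainer import PseudoConfig, TrainConfig

_GLOBAL_SEED: Optional[int] = None


def set_global_seed(seed: int) -> None:
    """Set the default seed used when a config does not specify one."""
    global _GLOBAL_SEED
    _GLOBAL_SEED = int(seed)


def get_global_seed() -> int:
    return 0 if _GLOBAL_SEED is None else _GLOBAL_SEED


@dataclass(frozen=True)
class DataConfig:
    n_total: int = 200
    labelled_fraction: float = 0.10
    n_test: int = 40

    def validate(self) -> "DataConfig":
        if self.n_total < 1:
            raise ConfigurationError("n_total must be >= 1")
        if not 0 < self.labelled_fraction <= 1:
            raise ConfigurationError("labelled_fraction must be in (0, 1]")
        return self


@dataclass(frozen=True)
class MetricsConfig:
    tolerance: Optional[float] = None  # None: scale 13 px with image width

    def resolve_tolerance(self, width: int) -> float:
        if self.tolerance is not None:
            return float(self.tolerance)
        return scaled_tolerance(width)


@dataclass(frozen=True)
class RunConfig:
    profile: str = "desk"
    scene: SceneConfig = field(default_factory=SceneConfig)
    data: DataConfig = field(default_factory=DataConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    metrics: MetricsConfig = field(default_factory=MetricsConfig)

    def validate(self) -> "RunConfig":
        self.scene.validate()
        self.data.validate()
        self.model.validate()
        self.train.validate()
        return self


PROFILES: Dict[str, Dict[str, Any]] = {
    "desk": {},
    "paper": {
        "model": {"depth": 6, "base_channels": 32},
        "train": {"epochs": 1000, "batch_size": 64,
                  "adversarial": {"steps": 25}},
        "scene": {"height": 512, "width": 512},
        "metrics": {"tolerance": 13.0},
    },
}


def _build(cls, values: Dict[str, Any], path: str):
    if not isinstance(values, dict):
        raise ConfigurationError(f"{path}: expected a mapping, got {type(values).__name__}")
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(values) - set(fields)
    if unknown:
        raise ConfigurationError(f"{path}: unknown key(s) {sorted(unknown)}")
    kwargs = {}
    for name, value in values.items():
        ftype = fields[name].type
        nested = _NESTED.get((cls, name))
        if nested is not None:
            kwargs[name] = _build(nested, value, f"{path}.{name}")
        elif name.endswith("_range") or name == "weak_kinds":
            kwargs[name] = tuple(value)
        elif name == "strong_augmentation" and value is not None:
            kwargs[name] = {op: tuple(rng) for op, rng in value.items()}
        else:
            kwargs[name] = value
    try:
        return cls(**kwargs)
    except TypeError as exc:
        raise ConfigurationError(f"{path}: {exc}") from exc


_NESTED = {
    (RunConfig, "scene"): SceneConfig,
    (RunConfig, "data"): DataConfig,
    (RunConfig, "model"): ModelConfig,
    (RunConfig, "train"): TrainConfig,
    (RunConfig, "metrics"): MetricsConfig,
    (TrainConfig, "pseudo"): PseudoConfig,
    (TrainConfig, "adversarial"): AdversarialConfig,
    (TrainConfig, "loss"): LossConfig,
}


def _deep_merge(base: Dict[str, Any], extra: Dict[str, Any]) -> Dict[str, Any]:
    out = dict(base)
    for key, value in extra.items():
        if isinstance(value, dict) and isinstance(out.get(key), dict):
            out[key] = _deep_merge(out[key], value)
        else:
            out[key] = value
    return out


def config_from_dict(raw: Dict[str, Any]) -> RunConfig:
    raw = dict(raw or {})
    profile = raw.get("profile", "desk")
    if profile not in PROFILES:
        raise ConfigurationError(
            f"unknown profile {profile!r}; choose from {sorted(PROFILES)}")
    merged = _deep_merge(PROFILES[profile], raw)
    merged.setdefault("profile", profile)
    cfg = _build(RunConfig, merged, "config")
    return cfg.validate()


def load_config(path: str) -> RunConfig:
    """Parse a YAML config, fill profile defaults, and validate the schema."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    cfg = config_from_dict(raw or {})
    if _GLOBAL_SEED is not None and "seed" not in str(raw):
        cfg = dataclasses.replace(
            cfg,
            scene=dataclasses.replace(cfg.scene, seed=_GLOBAL_SEED),
            model=dataclasses.replace(cfg.model, seed=_GLOBAL_SEED),
            train=dataclasses.replace(cfg.train, seed=_GLOBAL_SEED))
    return cfg


def config_to_dict(cfg: RunConfig) -> Dict[str, Any]:
    def convert(obj):
        if dataclasses.is_dataclass(obj):
            return {f.name: convert(getattr(obj, f.name))
                    for f in dataclasses.fields(obj)}
        if isinstance(obj, tuple):
            return [convert(v) for v in obj]
        if isinstance(obj, dict):
            return {k: convert(v) for k, v in obj.items()}
        return obj
    return convert(cfg)


def save_config(cfg: RunConfig, path: str) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(cfg), fh, sort_keys=False)
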