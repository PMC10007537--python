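"""Run configuration: a YAML/JSON-loadable schema covering the reward
weights, environment, reference generator, SAC hyperparameters and the
training protocol."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .environment import (
    DEFAULT_AMPLITUDES,
    DEFAULT_GAIT_PERIOD,
    DEFAULT_NOISE,
    DEFAULT_PHASES,
    WalkerParams,
)
from .errors import ConfigError
from .rewards import N_COMPONENTS, RewardWeights
from .sac import SACConfig
from .train import TrainConfig


@dataclass
class ReferenceConfig:
    """Parameters of the synthetic reference-IMU generator."""

    gait_period: float = DEFAULT_GAIT_PERIOD
    amplitudes: tuple[float, float, float] = DEFAULT_AMPLITUDES
    phases: tuple[float, float, float] = DEFAULT_PHASES
    drift: tuple[float, float, float] = (0.0, 0.0, 0.0)
    noise: float = DEFAULT_NOISE
    duration: float = 5.0
    dt: float = 0.01
    path: str | None = None  # load a recorded trace instead of generating


@dataclass
class RunConfig:
    """Top-level configuration of one experiment run."""

    name: str = "run"
    seed: int = 0
    use_imu_reward: bool = True
    component_weights: tuple[float, ...] | None = None  # None -> all ones
    w_step: float = 1.0
    w_vel: float = 1.0
    w_eff: float = 1.0
    difficulty: int = 1  # 1: fixed target (5, 0); 2: randomized (config hook)
    target: tuple[float, float] = (5.0, 0.0)
    reference: ReferenceConfig = field(default_factory=ReferenceConfig)
    walker: WalkerParams = field(default_factory=WalkerParams)
    train: TrainConfig = field(default_factory=TrainConfig)
    run_distillation: bool = False
    distill_steps: int = 100
    distill_batch: int = 128
    distill_lr: float = 1e-4
    distill_hidden: tuple[int, ...] = (128, 128)
    n_workers: int = 1  # >1 reserved; single-process mode is deterministic

    def __post_init__(self):
        if self.difficulty not in (1, 2):
            raise ConfigError(f"difficulty must be 1 or 2, got {self.difficulty}")
        if self.n_workers < 1:
            raise ConfigError("n_workers must be >= 1")
        if self.component_weights is not None and len(self.component_weights) != N_COMPONENTS:
            raise ConfigError(
                f"component_weights must have {N_COMPONENTS} entries"
            )

    def reward_weights(self) -> RewardWeights:
        if self.component_weights is not None:
            w = np.asarray(self.component_weights, dtype=np.float64)
        else:
            w = np.ones(N_COMPONENTS)
        if not self.use_imu_reward:
            w = w.copy()
            w[7:10] = 0.0
        return RewardWeights(
            w=w, w_step=self.w_step, w_vel=self.w_vel, w_eff=self.w_eff
        )

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _coerce_dataclass(cls, data: dict):
    """Build a dataclass from a plain dict, coercing nested blocks and
    rejecting unknown keys."""
    fields = {f.name: f for f in cls.__dataclass_fields__.values()}
    kwargs = {}
    for key, value in data.items():
        if key not in fields:
            raise ConfigError(f"unknown config key {key!r} for {cls.__name__}")
        kwargs[key] = value
    nested = {
        "reference": ReferenceConfig,
        "walker": WalkerParams,
        "train": TrainConfig,
        "sac": SACConfig,
    }
    for key, sub_cls in nested.items():
        if key in kwargs and isinstance(kwargs[key], dict):
            kwargs[key] = _coerce_dataclass(sub_cls, kwargs[key])
    for key in ("component_weights", "amplitudes", "phases", "drift",
                "target", "distill_hidden", "policy_hidden", "critic_hidden"):
        if key in kwargs and isinstance(kwargs[key], list):
            kwargs[key] = tuple(kwargs[key])
    return cls(**kwargs)


def load_config(path: str | Path) -> RunConfig:
    """Load a RunConfig from a YAML (or JSON — a YAML subset) file."""
    path = Path(path)
    try:
        data = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse config {path}: {exc}") from exc
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError(f"config root must be a mapping, got {type(data)}")
    if "train" in data and isinstance(data["train"], dict) and isinstance(
        data["train"].get("sac"), dict
    ):
        data["train"]["sac"] = _coerce_dataclass(SACConfig, data["train"]["sac"])
    return _coerce_dataclass(RunConfig, data)


def save_config(config: RunConfig, path: str | Path) -> None:
    # json round trip turns tuples into lists, which YAML can represent
    data = json.loads(json.dumps(config.to_dict(), default=str))
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))
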