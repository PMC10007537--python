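"""Reduced-scale paired comparison: IMU-constrained versus baseline reward.

For each seed, two agents are trained under identical conditions — same
walker, same synthetic reference trace, same training protocol and matched
seeds — differing only in whether the three IMU deviation rewards carry
weight 1 or weight 0. After training, each agent's deterministic rollout is
scored by (a) the mean per-axis RMSE of its pelvis orientation against the
reference and (b) the final smoothed return under the common baseline
scalarization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .environment import SyntheticWalker, WalkerParams, generate_reference_imu
from .eval_io import align_traces, moving_mean, rmse_per_axis
from .rewards import RewardWeights
from .sac import SACConfig
from .train import TrainConfig, evaluation_rollout, train_stage_one

# Desk-scale training protocol for the synthetic walker: small networks and
# a short fixed budget (30 epochs), sized so a full seed pair trains in
# about a minute on one CPU.
DESK_SAC = dict(
    lr_policy=3e-4,
    lr_critic=1e-3,
    lr_alpha=3e-4,
    policy_hidden=(64, 64),
    critic_hidden=(64, 64),
    batch_segments=8,
    n_step=5,
)
DESK_TRAIN = dict(
    epochs=60,
    episodes_per_epoch=2,
    updates_per_epoch=80,
    warmup_episodes=4,
    max_episode_steps=500,
)
EVAL_LAST_K = 5  # evaluation checkpoints averaged per run


def desk_train_config(**overrides) -> TrainConfig:
    sac_kwargs = dict(DESK_SAC)
    train_kwargs = dict(DESK_TRAIN)
    for k, v in overrides.items():
        if k in sac_kwargs:
            sac_kwargs[k] = v
        else:
            train_kwargs[k] = v
    return TrainConfig(sac=SACConfig(**sac_kwargs), **train_kwargs)


@dataclass
class PairResult:
    """Outcome of one matched-seed IMU-vs-baseline pair."""

    seed: int
    rmse_imu: tuple[float, float, float]
    rmse_baseline: tuple[float, float, float]
    final_return_imu: float
    final_return_baseline: float

    @property
    def rmse_mean_imu(self) -> float:
        return float(np.mean(self.rmse_imu))

    @property
    def rmse_mean_baseline(self) -> float:
        return float(np.mean(self.rmse_baseline))

    @property
    def rmse_improved(self) -> bool:
        return self.rmse_mean_imu < self.rmse_mean_baseline

    @property
    def return_not_lower(self) -> bool:
        return self.final_return_imu >= self.final_return_baseline

    @property
    def win(self) -> bool:
        return self.rmse_improved and self.return_not_lower


def run_single(
    weights: RewardWeights,
    seed: int,
    train_cfg: TrainConfig,
    walker_params: WalkerParams | None = None,
    smoothing_window: int = 10,
    eval_last_k: int = EVAL_LAST_K,
) -> tuple[tuple[float, float, float], float]:
    """Train one agent; return (per-axis RMSE, final smoothed eval return).

    The RMSE is the average over deterministic evaluation rollouts of the
    last ``eval_last_k`` epochs' policies, damping single-checkpoint
    jitter; the return is the final value of the smoothed learning curve.
    """
    params = walker_params or WalkerParams()
    reference = generate_reference_imu(
        duration=train_cfg.max_episode_steps * params.dt,
        dt=params.dt,
        seed=seed,
    )
    walker = SyntheticWalker(params)
    result = train_stage_one(
        walker, reference, weights, train_cfg, seed=seed,
        eval_last_k=max(1, eval_last_k),
    )
    rmse = tuple(
        float(np.mean([rec["rmse"][ax] for rec in result.eval_records]))
        for ax in range(3)
    )
    smoothed = moving_mean(result.curve[:, 1], smoothing_window)
    return rmse, float(smoothed[-1])


def run_pair(
    seed: int,
    train_cfg: TrainConfig | None = None,
    walker_params: WalkerParams | None = None,
) -> PairResult:
    """One matched-seed pair: identical everything except the IMU weights."""
    cfg = train_cfg or desk_train_config()
    rmse_imu, ret_imu = run_single(RewardWeights(), seed, cfg, walker_params)
    rmse_base, ret_base = run_single(
        RewardWeights.baseline(), seed, cfg, walker_params
    )
    return PairResult(
        seed=seed,
        rmse_imu=rmse_imu,
        rmse_baseline=rmse_base,
        final_return_imu=ret_imu,
        final_return_baseline=ret_base,
    )


def run_paired_comparison(
    n_pairs: int = 5,
    base_seed: int = 0,
    train_cfg: TrainConfig | None = None,
    walker_params: WalkerParams | None = None,
) -> list[PairResult]:
    """Run the matched-seed comparison over ``n_pairs`` seeds."""
    seeds = [int(s.generate_state(1)[0] % (2**31))
             for s in np.random.SeedSequence(base_seed).spawn(n_pairs)]
    return [run_pair(s, train_cfg, walker_params) for s in seeds]


def summarize_pairs(pairs: list[PairResult]) -> dict:
    """Aggregate win counts and mean RMSEs over seed pairs."""
    return {
        "n_pairs": len(pairs),
        "rmse_wins": sum(p.rmse_improved for p in pairs),
        "return_wins": sum(p.return_not_lower for p in pairs),
        "joint_wins": sum(p.win for p in pairs),
        "mean_rmse_imu": float(np.mean([p.rmse_mean_imu for p in pairs])),
        "mean_rmse_baseline": float(
            np.mean([p.rmse_mean_baseline for p in pairs])
        ),
        "mean_final_return_imu": float(
            np.mean([p.final_return_imu for p in pairs])
        ),
        "mean_final_return_baseline": float(
            np.mean([p.final_return_baseline for p in pairs])
        ),
    }
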