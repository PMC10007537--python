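"""Stage-one training loop: collect walker episodes, assemble reward
vectors against the reference IMU trace, and update the multivariate SAC
learner from prioritized segment replay.

Learning curves are recorded per epoch as (mean, min, max) of the episode
returns. Returns are scalarized with a fixed *evaluation* weight vector —
by default the baseline weights with the IMU components zeroed — so curves
from IMU-constrained and baseline configurations live on one common scale
and remain comparable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .environment import (
    IMUReferenceTrace,
    SyntheticWalker,
    observe_imu,
)
from .replay import SegmentReplay, Transition
from .rewards import (
    IMUTriplet,
    RewardVector,
    RewardWeights,
    assemble_and_scalarize,
    assemble_reward_vector,
)
from .sac import SACAgent, SACConfig


@dataclass
class TrainConfig:
    """Protocol of one stage-one run on the synthetic walker."""

    epochs: int = 30
    episodes_per_epoch: int = 2
    updates_per_epoch: int = 40
    warmup_episodes: int = 2  # exploration episodes seeded before learning
    warmup_gait_noise: float = 0.15  # sd of excitation noise around the
    # open-loop gait fixture during warmup; None/negative -> uniform random
    max_episode_steps: int = 500
    replay_capacity: int = 250_000
    segment_length: int = 10
    eta: float = 0.9
    sac: SACConfig = field(default_factory=SACConfig)


@dataclass
class EpisodeLog:
    """Per-episode record: returns under the run's own weights and under the
    common evaluation weights, plus the collected reward vectors."""

    return_own: float
    return_eval: float
    steps: int
    fell: bool
    reward_vectors: list[RewardVector]


def rollout_episode(
    walker: SyntheticWalker,
    agent: SACAgent | None,
    reference: IMUReferenceTrace,
    weights: RewardWeights,
    eval_weights: RewardWeights,
    replay: SegmentReplay | None,
    rng: np.random.Generator,
    max_steps: int = 500,
    random_actions: bool = False,
    deterministic: bool = False,
    record_imu: bool = False,
    gait_noise: float | None = None,
):
    """Run one episode; optionally feed its transitions into the replay.

    Returns (EpisodeLog, observed IMU angle array or None).
    """
    obs = walker.reset()
    episode: list[Transition] = []
    rvecs: list[RewardVector] = []
    imu_obs_log = [] if record_imu else None
    path_log = [] if record_imu else None
    ret_own = 0.0
    ret_eval = 0.0
    fell = False
    eid = replay.next_episode_id() if replay is not None else 0
    alpha = agent.temp.alpha if agent is not None else 0.0
    n_ref = len(reference)
    for t in range(max_steps):
        if gait_noise is not None and gait_noise >= 0:
            # exploration around the open-loop gait fixture
            from .environment import reference_gait_excitation

            action = np.clip(
                reference_gait_excitation(walker.state.phase)
                + rng.normal(0.0, gait_noise, size=walker.ACTION_DIM),
                0.0, 1.0,
            )
            log_prob = 0.0
        elif random_actions or agent is None:
            action = rng.uniform(0.0, 1.0, size=walker.ACTION_DIM)
            log_prob = 0.0
        else:
            action, log_prob = agent.act(obs, deterministic=deterministic)
        next_obs, kin, done = walker.step(action)
        imu_col = reference.triplet_at(min(t, n_ref - 1))
        imu_sim = observe_imu(walker.state)
        if record_imu:
            imu_obs_log.append(imu_sim.as_array())
            path_log.append([walker.state.x, walker.state.y])
        rvec = assemble_reward_vector(
            kin, np.clip(action, 0.0, 1.0), weights, alpha, log_prob,
            imu_col, imu_sim,
        )
        rvecs.append(rvec)
        ret_own += assemble_and_scalarize(rvec, weights)
        ret_eval += assemble_and_scalarize(rvec, eval_weights)
        fell = fell or kin.fallen
        episode.append(
            Transition(
                observation=obs, action=np.clip(action, 0.0, 1.0),
                reward=rvec.components, next_observation=next_obs,
                done=done and kin.fallen,  # timeout/arrival is not terminal
                episode_id=eid, t=t,
            )
        )
        obs = next_obs
        if done:
            break
    if replay is not None:
        replay.add_episode(episode)
    log = EpisodeLog(
        return_own=ret_own, return_eval=ret_eval, steps=len(episode),
        fell=fell, reward_vectors=rvecs,
    )
    imu_arr = np.array(imu_obs_log) if record_imu else None
    path_arr = np.array(path_log) if record_imu else None
    return log, imu_arr, path_arr


@dataclass
class TrainResult:
    """Artifacts of one stage-one run."""

    agent: SACAgent
    replay: SegmentReplay
    curve: "np.ndarray"  # (epochs, 4): epoch, mean, min, max of eval return
    episode_logs: list[EpisodeLog]
    reference: IMUReferenceTrace
    eval_records: list[dict] = field(default_factory=list)


def train_stage_one(
    walker: SyntheticWalker,
    reference: IMUReferenceTrace,
    weights: RewardWeights,
    train_cfg: TrainConfig | None = None,
    seed: int = 0,
    eval_weights: RewardWeights | None = None,
    eval_last_k: int = 0,
) -> TrainResult:
    """Train a multivariate SAC agent on the synthetic walker.

    Fully deterministic for a given seed in this single-process mode: one
    seed sequence fans out to agent initialization, the action sampler, the
    warmup stream, and replay sampling.

    With ``eval_last_k`` > 0 a deterministic evaluation rollout is run on a
    separate walker instance after each of the last k epochs and recorded in
    ``TrainResult.eval_records`` (epoch, per-axis orientation RMSE against
    the reference, evaluation return, final forward position). Scoring a
    run by the average of these records rather than by the single final
    checkpoint damps checkpoint-to-checkpoint jitter.
    """
    cfg = train_cfg or TrainConfig()
    eval_weights = eval_weights or RewardWeights.baseline()
    ss = np.random.SeedSequence(seed)
    agent_seed, env_seed = ss.spawn(2)
    agent = SACAgent(
        walker.OBS_DIM, walker.ACTION_DIM, weights, cfg.sac,
        seed=int(agent_seed.generate_state(1)[0] % (2**31)),
    )
    env_rng = np.random.default_rng(env_seed)
    replay = SegmentReplay(
        capacity_transitions=cfg.replay_capacity,
        segment_length=cfg.segment_length,
        eta=cfg.eta,
    )
    logs: list[EpisodeLog] = []
    gait_noise = cfg.warmup_gait_noise
    if gait_noise is not None and gait_noise < 0:
        gait_noise = None
    for _ in range(cfg.warmup_episodes):
        _ = rollout_episode(
            walker, agent, reference, weights, eval_weights, replay,
            env_rng, cfg.max_episode_steps, random_actions=True,
            gait_noise=gait_noise,
        )
    curve_rows = []
    eval_records: list[dict] = []
    for epoch in range(cfg.epochs):
        epoch_returns = []
        for _ in range(cfg.episodes_per_epoch):
            log, _, _ = rollout_episode(
                walker, agent, reference, weights, eval_weights, replay,
                env_rng, cfg.max_episode_steps,
            )
            logs.append(log)
            epoch_returns.append(log.return_eval)
        for _ in range(cfg.updates_per_epoch):
            agent.update(replay)
        curve_rows.append(
            [epoch, float(np.mean(epoch_returns)),
             float(np.min(epoch_returns)), float(np.max(epoch_returns))]
        )
        if eval_last_k > 0 and epoch >= cfg.epochs - eval_last_k:
            from .eval_io import align_traces, rmse_per_axis  # late: no cycle

            eval_walker = SyntheticWalker(
                walker.params, target=walker.target.copy(),
                speed_profile=walker.speed_profile,
            )
            elog, imu_obs, _ = evaluation_rollout(
                eval_walker, agent, reference, weights,
                max_steps=cfg.max_episode_steps, seed=seed,
            )
            ref_a, obs_a = align_traces(reference, imu_obs)
            rmse = rmse_per_axis(ref_a, obs_a)
            eval_records.append(
                {"epoch": epoch, "rmse": rmse,
                 "return_eval": elog.return_eval,
                 "x_final": float(eval_walker.state.x)}
            )
    return TrainResult(
        agent=agent, replay=replay, curve=np.array(curve_rows),
        episode_logs=logs, reference=reference, eval_records=eval_records,
    )


def evaluation_rollout(
    walker: SyntheticWalker,
    agent: SACAgent,
    reference: IMUReferenceTrace,
    weights: RewardWeights,
    max_steps: int = 500,
    seed: int = 0,
):
    """Deterministic-policy rollout for evaluation.

    Returns (EpisodeLog, observed IMU angles (T, 3), pelvis path (T, 2)).
    Reward bookkeeping here is recomputed from the rollout, independent of
    any training-time reward traces.
    """
    rng = np.random.default_rng(seed)
    log, imu, path = rollout_episode(
        walker, agent, reference, weights, RewardWeights.baseline(), None,
        rng, max_steps, deterministic=True, record_imu=True,
    )
    return log, imu, path
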