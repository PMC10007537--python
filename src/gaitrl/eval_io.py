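"""IMU trace I/O, RMSE evaluation, learning-curve aggregation, and the
end-to-end experiment runner.

Evaluation is deliberately independent of the training path: RMSEs are
recomputed from logged rollout trajectories with their own elementwise
arithmetic, never reused from training-time reward traces.
"""

from __future__ import annotations

import json
import platform
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .environment import (
    IMUReferenceTrace,
    SyntheticWalker,
    generate_reference_imu,
)
from .errors import AlignmentError, ContractError, FormatError
from .rewards import REWARD_COMPONENTS, RewardWeights, reward_trace_frame, wrap_angle
from .train import TrainConfig, evaluation_rollout, train_stage_one

IMU_COLUMNS = ("time_s", "roll_rad", "pitch_rad", "yaw_rad")


# ---------------------------------------------------------------------------
# IMU table I/O


def save_imu_table(trace: IMUReferenceTrace, path: str | Path) -> None:
    """Write a trace as CSV with columns time_s, roll_rad, pitch_rad, yaw_rad."""
    df = pd.DataFrame(
        {
            "time_s": trace.times,
            "roll_rad": trace.angles[:, 0],
            "pitch_rad": trace.angles[:, 1],
            "yaw_rad": trace.angles[:, 2],
        }
    )
    df.to_csv(path, index=False, float_format="%.12g")


def load_imu_table(path: str | Path, dt: float = 0.01) -> IMUReferenceTrace:
    """Read an IMU CSV table and resample it onto the uniform dt grid.

    Non-uniform timestamps are linearly interpolated with endpoints
    preserved; a trace already on the grid is returned unchanged.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pandas raises several parser error types
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    missing = [c for c in IMU_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    if len(df) < 2:
        raise FormatError(f"{path}: need at least 2 rows, got {len(df)}")
    t = df["time_s"].to_numpy(dtype=np.float64)
    if not np.all(np.isfinite(t)):
        raise FormatError(f"{path}: non-finite timestamps")
    bad = np.where(np.diff(t) <= 0)[0]
    if bad.size:
        raise FormatError(
            f"{path}: non-monotone timestamps at rows {bad[:5].tolist()}"
        )
    angles_in = df[["roll_rad", "pitch_rad", "yaw_rad"]].to_numpy(np.float64)
    if not np.all(np.isfinite(angles_in)):
        raise FormatError(f"{path}: non-finite angle values")
    step = np.diff(t)
    on_grid = (
        abs(t[0]) < 1e-12 and np.allclose(step, dt, rtol=0, atol=1e-9)
    )
    if on_grid:
        grid = t
        angles = angles_in
    else:
        grid = np.arange(t[0], t[-1] + dt / 2, dt)
        angles = np.column_stack(
            [np.interp(grid, t, angles_in[:, k]) for k in range(3)]
        )
    return IMUReferenceTrace(
        dt=dt, angles=angles, metadata={"source": str(path)}
    )


# ---------------------------------------------------------------------------
# RMSE


def rmse_per_axis(
    reference: IMUReferenceTrace | np.ndarray,
    observed: IMUReferenceTrace | np.ndarray,
) -> tuple[float, float, float]:
    """Per-axis root-mean-square wrapped angular deviation (roll, pitch, yaw).

    Residuals are wrapped to (-pi, pi] before squaring so a seam crossing at
    +/-pi does not register as a ~2*pi error.
    """
    a = reference.angles if isinstance(reference, IMUReferenceTrace) else np.asarray(reference)
    b = observed.angles if isinstance(observed, IMUReferenceTrace) else np.asarray(observed)
    if a.shape != b.shape:
        raise AlignmentError(
            f"trace length/shape mismatch after alignment: {a.shape} vs {b.shape}"
        )
    diff = wrap_angle(a - b)
    r = np.sqrt(np.mean(diff**2, axis=0))
    return float(r[0]), float(r[1]), float(r[2])


def align_traces(
    reference: IMUReferenceTrace, observed: IMUReferenceTrace | np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Align two traces at episode start and crop to the common length."""
    a = reference.angles
    b = observed.angles if isinstance(observed, IMUReferenceTrace) else np.asarray(observed)
    n = min(a.shape[0], b.shape[0])
    if n == 0:
        raise AlignmentError("no overlapping samples")
    return a[:n], b[:n]


# ---------------------------------------------------------------------------
# learning curves


@dataclass
class LearningCurve:
    """Per-epoch scalarized-return statistics for one named configuration."""

    name: str
    epochs: np.ndarray
    mean: np.ndarray
    min: np.ndarray
    max: np.ndarray

    def __post_init__(self):
        if np.any(np.diff(self.epochs) <= 0):
            raise ContractError("epochs must be strictly increasing")
        for arr in (self.mean, self.min, self.max):
            if not np.all(np.isfinite(arr)):
                raise ContractError("non-finite curve values")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"epoch": self.epochs, "mean": self.mean,
             "min": self.min, "max": self.max}
        )


def moving_mean(x: np.ndarray, window: int) -> np.ndarray:
    """Trailing moving mean with a growing head window (min_periods = 1);
    window 1 is the identity."""
    if window < 1:
        raise ContractError("smoothing window must be >= 1")
    x = np.asarray(x, dtype=np.float64)
    out = np.empty_like(x)
    for i in range(x.size):
        out[i] = x[max(0, i - window + 1) : i + 1].mean()
    return out


def aggregate_learning_curves(
    run_logs: dict[str, np.ndarray], window: int = 10
) -> dict[str, LearningCurve]:
    """Smooth per-configuration epoch curves onto a common axis.

    ``run_logs`` maps a configuration name (e.g. "imu", "baseline") to an
    (epochs, 4) array of [epoch, mean, min, max] rows as produced by
    ``train_stage_one``.
    """
    if not run_logs:
        raise ContractError("no run logs to aggregate")
    curves = {}
    for name, rows in run_logs.items():
        rows = np.atleast_2d(np.asarray(rows, dtype=np.float64))
        if rows.shape[0] < 1 or rows.shape[1] != 4:
            raise ContractError(f"run log {name!r} must be (epochs, 4)")
        curves[name] = LearningCurve(
            name=name,
            epochs=rows[:, 0],
            mean=moving_mean(rows[:, 1], window),
            min=moving_mean(rows[:, 2], window),
            max=moving_mean(rows[:, 3], window),
        )
    return curves


# ---------------------------------------------------------------------------
# experiment runner


def run_experiment(config, out_dir: str | Path) -> dict:
    """Run the configured experiment end to end and emit its artifacts.

    Stage one trains the multivariate SAC agent on the synthetic walker;
    optionally stage two distills it into target-velocity-conditioned
    networks. Emits a checkpoint, learning-curve CSV, rollout trajectory
    CSV, reward-trace CSV, per-axis RMSE report and a metadata record.
    Returns the artifact manifest.
    """
    from . import __version__
    from .config import RunConfig, save_config  # local import avoids a cycle
    from .distill import distill_stage_two
    from .environment import make_target_field

    assert isinstance(config, RunConfig)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ref_cfg = config.reference
    if ref_cfg.path:
        reference = load_imu_table(ref_cfg.path, dt=ref_cfg.dt)
    else:
        reference = generate_reference_imu(
            gait_period=ref_cfg.gait_period,
            amplitudes=ref_cfg.amplitudes,
            phases=ref_cfg.phases,
            drift=ref_cfg.drift,
            noise=ref_cfg.noise,
            duration=ref_cfg.duration,
            dt=ref_cfg.dt,
            seed=config.seed,
        )
    walker = SyntheticWalker(config.walker, target=np.asarray(config.target))
    weights = config.reward_weights()
    result = train_stage_one(
        walker, reference, weights, config.train, seed=config.seed
    )

    # evaluation rollout, recomputed independently of training logs
    eval_walker = SyntheticWalker(config.walker, target=np.asarray(config.target))
    log, imu_obs, path_xy = evaluation_rollout(
        eval_walker, result.agent, reference, weights,
        max_steps=config.train.max_episode_steps, seed=config.seed,
    )
    ref_a, obs_a = align_traces(reference, imu_obs)
    rmse = rmse_per_axis(ref_a, obs_a)

    manifest = {}

    ckpt = out / "stage_one.npz"
    result.agent.save(ckpt)
    manifest["checkpoint"] = str(ckpt)

    curve_csv = out / "learning_curve.csv"
    pd.DataFrame(
        result.curve, columns=["epoch", "mean", "min", "max"]
    ).to_csv(curve_csv, index=False, float_format="%.12g")
    manifest["learning_curve"] = str(curve_csv)

    roll_csv = out / "rollout_trajectory.csv"
    n = imu_obs.shape[0]
    pd.DataFrame(
        {
            "time_s": np.arange(n) * config.walker.dt,
            "roll_rad": imu_obs[:, 0],
            "pitch_rad": imu_obs[:, 1],
            "yaw_rad": imu_obs[:, 2],
            "x_m": path_xy[:, 0],
            "y_m": path_xy[:, 1],
        }
    ).to_csv(roll_csv, index=False, float_format="%.12g")
    manifest["rollout_trajectory"] = str(roll_csv)

    trace_csv = out / "reward_trace.csv"
    reward_trace_frame(log.reward_vectors, dt=config.walker.dt).to_csv(
        trace_csv, index=False, float_format="%.12g"
    )
    manifest["reward_trace"] = str(trace_csv)

    ref_csv = out / "reference_imu.csv"
    save_imu_table(reference, ref_csv)
    manifest["reference_imu"] = str(ref_csv)

    rmse_report = out / "rmse_report.json"
    rmse_report.write_text(
        json.dumps(
            {"rmse_roll": rmse[0], "rmse_pitch": rmse[1], "rmse_yaw": rmse[2],
             "samples": int(ref_a.shape[0])},
            indent=2,
        )
    )
    manifest["rmse_report"] = str(rmse_report)

    if config.run_distillation:
        field = make_target_field(np.zeros(2), np.asarray(config.target))
        student, history = distill_stage_two(
            result.agent.policy, result.agent.critics[0], result.replay,
            field, weights, hidden=config.distill_hidden,
            steps=config.distill_steps, batch_size=config.distill_batch,
            lr=config.distill_lr, seed=config.seed,
        )
        dckpt = out / "stage_two.npz"
        arrays = {f"policy/{k}": v for k, v in student.policy.params.items()}
        arrays.update({f"critic/{k}": v for k, v in student.critic.params.items()})
        np.savez(dckpt, **arrays)
        manifest["stage_two_checkpoint"] = str(dckpt)
        manifest["distill_final_losses"] = history[-1] if history else {}

    meta = out / "metadata.json"
    meta.write_text(
        json.dumps(
            {
                "seed": config.seed,
                "config_hash": config.config_hash(),
                "gaitrl_version": __version__,
                "numpy_version": np.__version__,
                "python_version": platform.python_version(),
                "reward_components": list(REWARD_COMPONENTS),
                "smoothing_window_default": 10,
            },
            indent=2,
        )
    )
    manifest["metadata"] = str(meta)
    save_config(config, out / "config.yaml")
    manifest["config"] = str(out / "config.yaml")
    manifest["rmse"] = {"roll": rmse[0], "pitch": rmse[1], "yaw": rmse[2]}
    manifest["final_eval_return"] = log.return_eval
    return manifest
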