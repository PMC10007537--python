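"""Reward terms for inertia-constrained locomotion learning.

The reward is a 10-component vector per timestep,

    r = [r_env, r_clp, r_vdp, r_pvb, r_dep, r_tab,
         r_entropy, r_IMUroll, r_IMUpitch, r_IMUyaw]

combining trajectory-optimization terms (alive bonus, step reward, velocity
and effort costs, shaping terms) with three bio-inspired terms that penalize
the absolute deviation of the simulated pelvis orientation from a reference
IMU recording, axis by axis. A scalar reward, where one is needed, is the
weighted sum of the components; each component also gets its own critic head
so terms can be added or removed without interfering with one another.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import ShapeError, ValidationError

REWARD_COMPONENTS: tuple[str, ...] = (
    "r_env",
    "r_clp",
    "r_vdp",
    "r_pvb",
    "r_dep",
    "r_tab",
    "r_entropy",
    "r_imu_roll",
    "r_imu_pitch",
    "r_imu_yaw",
)
N_COMPONENTS = len(REWARD_COMPONENTS)

ALIVE_BONUS = 0.1  # per non-fallen timestep


def wrap_angle(a):
    """Wrap angle(s) to the half-open interval (-pi, pi]."""
    a = np.asarray(a, dtype=np.float64)
    out = -(np.mod(-a + np.pi, 2.0 * np.pi) - np.pi)
    return out if out.ndim else float(out)


@dataclass
class IMUTriplet:
    """Pelvis orientation as (roll, pitch, yaw) Euler angles in radians."""

    roll: float
    pitch: float
    yaw: float

    def __post_init__(self):
        vals = (self.roll, self.pitch, self.yaw)
        if not all(np.isfinite(v) for v in vals):
            raise ValidationError(f"non-finite IMU angles {vals}")
        self.roll = wrap_angle(self.roll)
        self.pitch = wrap_angle(self.pitch)
        self.yaw = wrap_angle(self.yaw)

    def as_array(self) -> np.ndarray:
        return np.array([self.roll, self.pitch, self.yaw])


@dataclass
class BodyKinematics:
    """Per-timestep kinematic summary the reward terms consume.

    Positions are radius vectors in meters (3D, ground plane z = 0),
    velocities in m/s, activations unitless in [0, 1].
    """

    v_body: np.ndarray  # pelvis planar velocity (2,)
    v_vel: np.ndarray  # pelvis velocity used in the velocity cost (2,)
    v_tgt: np.ndarray  # local target velocity at the pelvis cell (2,)
    r_head: np.ndarray  # (3,)
    r_pelvis: np.ndarray  # (3,)
    r_left: np.ndarray  # (3,)
    r_right: np.ndarray  # (3,)
    activations: np.ndarray  # per-muscle, in [0, 1]
    in_step: bool
    dt: float = 0.01
    fallen: bool = False

    def __post_init__(self):
        for name in ("v_body", "v_vel", "v_tgt", "r_head", "r_pelvis",
                     "r_left", "r_right", "activations"):
            arr = np.asarray(getattr(self, name), dtype=np.float64)
            setattr(self, name, arr)
            if not np.all(np.isfinite(arr)):
                raise ValidationError(f"non-finite values in {name}")
        if self.dt <= 0:
            raise ValidationError(f"dt must be positive, got {self.dt}")
        acts = self.activations
        if np.any(acts < -1e-12) or np.any(acts > 1.0 + 1e-12):
            raise ValidationError("activations outside [0, 1]")


@dataclass
class RewardWeights:
    """Per-component scalarization weights plus the weights inside r_env.

    The IMU deviation terms default to weight 1; setting them to 0 recovers
    the trajectory-optimization-only baseline exactly.
    """

    w: np.ndarray = field(
        default_factory=lambda: np.ones(N_COMPONENTS, dtype=np.float64)
    )
    w_step: float = 1.0
    w_vel: float = 1.0
    w_eff: float = 1.0

    def __post_init__(self):
        self.w = np.asarray(self.w, dtype=np.float64)
        if self.w.shape != (N_COMPONENTS,):
            raise ShapeError(
                f"expected {N_COMPONENTS} weights, got shape {self.w.shape}"
            )
        if np.any(self.w < 0):
            raise ValidationError("component weights must be non-negative")

    @classmethod
    def baseline(cls) -> "RewardWeights":
        """Weights with the three IMU components zeroed (no-IMU baseline)."""
        w = np.ones(N_COMPONENTS)
        w[7:10] = 0.0
        return cls(w=w)

    def component_weight(self, name: str) -> float:
        return float(self.w[REWARD_COMPONENTS.index(name)])


@dataclass
class RewardVector:
    """Ordered 10-component reward with its component names."""

    components: np.ndarray
    names: tuple[str, ...] = REWARD_COMPONENTS

    def __post_init__(self):
        self.components = np.asarray(self.components, dtype=np.float64)
        if self.components.shape != (len(self.names),):
            raise ShapeError(
                f"expected {len(self.names)} components, got "
                f"{self.components.shape}"
            )
        if not np.all(np.isfinite(self.components)):
            raise ValidationError("non-finite reward components")


# ---------------------------------------------------------------------------
# trajectory-optimization reward terms


def tor_reward_terms(
    traj: Sequence[BodyKinematics], weights: RewardWeights
) -> tuple[float, float, float, float, float]:
    """Windowed trajectory-optimization terms over a kinematic trajectory.

    Returns ``(r_alive, r_step, c_vel, c_eff, r_env)`` where

    * ``r_alive`` — 0.1 per non-fallen timestep,
    * ``r_step``  — integrated in-step time, sum of in-step dt,
    * ``c_vel``   — norm of the in-step time integral of (v_vel - v_tgt),
    * ``c_eff``   — in-step time integral of the summed squared activations,
    * ``r_env``   — r_alive + w_step*r_step - w_vel*c_vel - w_eff*c_eff.
    """
    if len(traj) == 0:
        raise ValidationError("empty trajectory")
    dt0 = traj[0].dt
    for k in traj:
        if abs(k.dt - dt0) > 1e-12:
            raise ValidationError("all timesteps must share one dt")

    r_alive = ALIVE_BONUS * sum(1 for k in traj if not k.fallen)
    r_step = sum(k.dt for k in traj if k.in_step)
    vel_integral = np.zeros(2)
    c_eff = 0.0
    for k in traj:
        if k.in_step:
            vel_integral += (k.v_vel - k.v_tgt) * k.dt
            c_eff += float(np.sum(k.activations**2)) * k.dt
    c_vel = float(np.linalg.norm(vel_integral))
    r_env = (
        r_alive
        + weights.w_step * r_step
        - weights.w_vel * c_vel
        - weights.w_eff * c_eff
    )
    return float(r_alive), float(r_step), c_vel, float(c_eff), float(r_env)


def env_reward_step(kin: BodyKinematics, weights: RewardWeights) -> float:
    """Per-timestep decomposition of r_env used during online training.

    The windowed ``c_vel`` of :func:`tor_reward_terms` is a norm of a time
    integral and is not additive across timesteps; online learning needs a
    per-step signal, so the per-step velocity cost uses the norm of the
    instantaneous deviation instead. Summed over a window with zero deviation
    or all-out-of-step timesteps the two agree.
    """
    r = 0.0 if kin.fallen else ALIVE_BONUS
    if kin.in_step:
        r += weights.w_step * kin.dt
        r -= weights.w_vel * float(np.linalg.norm(kin.v_vel - kin.v_tgt)) * kin.dt
        r -= weights.w_eff * float(np.sum(kin.activations**2)) * kin.dt
    return float(r)


def crossing_legs_score(kin: BodyKinematics) -> float:
    """Signed scalar triple product of the leg/torso geometry.

    ``s = ((r_right - r_pelvis) x (r_left - r_pelvis)) . (r_head - r_pelvis)``
    is positive for uncrossed legs under the right-handed convention
    (x forward, y left, z up) and flips sign when the feet cross the
    body midline.
    """
    u = kin.r_right - kin.r_pelvis
    v = kin.r_left - kin.r_pelvis
    w = kin.r_head - kin.r_pelvis
    if np.linalg.norm(w) < 1e-12:
        raise ValidationError("head coincides with pelvis: no torso direction")
    return float(np.dot(np.cross(u, v), w))


def target_achievement_bonus(v_tgt_norm: float) -> float:
    """Piecewise stopping bonus on the local target-speed magnitude.

    0 above 0.7 m/s, 0.1 on (0.5, 0.7], and ``1 - 3.5 * |v_tgt|^2`` at or
    below 0.5 m/s (equal to 1 when the commanded speed is zero, i.e. the
    agent stands on the target).
    """
    if v_tgt_norm < 0:
        raise ValidationError("speed magnitude must be non-negative")
    if v_tgt_norm > 0.7:
        return 0.0
    if v_tgt_norm > 0.5:
        return 0.1
    return 1.0 - 3.5 * v_tgt_norm**2


def shaping_terms(
    kin: BodyKinematics, action: np.ndarray
) -> tuple[float, float, float, float, float]:
    """Dense shaping terms ``(r_clp, r_pvb, r_vdp, r_dep, r_tab)``.

    * crossing-legs penalty: min(0, triple-product score), <= 0
    * pelvis velocity bonus: ||v_body||
    * velocity deviation penalty: -||v_body - v_tgt|| while in step
    * dense effort penalty: -||action||
    * target achievement bonus: piecewise rule on ||v_tgt||
    """
    action = np.asarray(action, dtype=np.float64)
    if np.any(action < -1e-12) or np.any(action > 1.0 + 1e-12):
        raise ValidationError("action outside [0, 1]")
    r_clp = min(0.0, crossing_legs_score(kin))
    r_pvb = float(np.linalg.norm(kin.v_body))
    r_vdp = (
        -float(np.linalg.norm(kin.v_body - kin.v_tgt)) if kin.in_step else 0.0
    )
    r_dep = -float(np.linalg.norm(action))
    r_tab = target_achievement_bonus(float(np.linalg.norm(kin.v_tgt)))
    return r_clp, r_pvb, r_vdp, r_dep, r_tab


def imu_terms(
    collected: IMUTriplet, observed: IMUTriplet
) -> tuple[float, float, float]:
    """Bio-inspired deviation rewards, one per axis.

    Each term is the negative absolute angular difference between the
    reference (collected) and simulated (observed) pelvis orientation,
    wrapped to (-pi, pi] before taking the magnitude so a crossing of the
    +/-pi seam does not look like a two-pi error.
    """
    diff = wrap_angle(collected.as_array() - observed.as_array())
    r = -np.abs(diff)
    return float(r[0]), float(r[1]), float(r[2])


def entropy_term(alpha: float, log_prob: float) -> float:
    """Entropy bonus ``alpha * H`` with ``H = -log pi(a|s)`` at the sample."""
    if alpha < 0:
        raise ValidationError(f"temperature must be non-negative, got {alpha}")
    return float(alpha * (-log_prob))


def assemble_reward_vector(
    kin: BodyKinematics,
    action: np.ndarray,
    weights: RewardWeights,
    alpha: float,
    log_prob: float,
    imu_collected: IMUTriplet,
    imu_observed: IMUTriplet,
) -> RewardVector:
    """Build the full 10-component per-timestep reward vector."""
    r_env = env_reward_step(kin, weights)
    r_clp, r_pvb, r_vdp, r_dep, r_tab = shaping_terms(kin, action)
    r_ent = entropy_term(alpha, log_prob)
    r_roll, r_pitch, r_yaw = imu_terms(imu_collected, imu_observed)
    return RewardVector(
        np.array(
            [r_env, r_clp, r_vdp, r_pvb, r_dep, r_tab,
             r_ent, r_roll, r_pitch, r_yaw]
        )
    )


def assemble_and_scalarize(rvec: RewardVector, weights: RewardWeights) -> float:
    """Weighted sum of the reward components (the scalar reward)."""
    if rvec.components.shape != weights.w.shape:
        raise ShapeError(
            f"component/weight length mismatch: {rvec.components.shape} vs "
            f"{weights.w.shape}"
        )
    return float(np.dot(rvec.components, weights.w))


def reward_trace_frame(reward_vectors: Sequence[RewardVector], dt: float = 0.01):
    """Reward-vector trace as a pandas DataFrame, one named column per
    component plus the timestep, ready for CSV export."""
    import pandas as pd

    data = {"time_s": np.arange(len(reward_vectors)) * dt}
    mat = np.array([rv.components for rv in reward_vectors])
    for j, name in enumerate(REWARD_COMPONENTS):
        data[name] = mat[:, j] if len(reward_vectors) else np.array([])
    return pd.DataFrame(data)
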