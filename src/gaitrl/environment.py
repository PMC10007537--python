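"""Locomotion environments: interface contract, synthetic planar walker,
target-velocity field, and the synthetic reference-IMU generator.

The environment contract is deliberately narrow: ``reset(seed) -> obs`` and
``step(action) -> (obs, BodyKinematics, done)``. Reward computation never
reaches inside the dynamics; everything a reward term needs is in the
returned :class:`~gaitrl.rewards.BodyKinematics`.

The shipped walker is a simplified planar biped driven by first-order
muscle-activation dynamics and a periodic foot-contact phase oscillator.
It is not a physiological musculoskeletal simulator: it exists so the full
training/replay/distillation stack can run end-to-end on one CPU. An
external musculoskeletal simulator (e.g. an OpenSim-based one) can be
plugged in by implementing the same contract; the full-model layout
constants (97-dim state, 22 muscles) are kept as the contract for that case.

Coordinate conventions: right-handed world frame, x toward the default
target, z up; agent starts at (0, 0), default target (5, 0). Pelvis
orientation is intrinsic Z-X-Y Euler (yaw about z, then roll about x, then
pitch about y), all wrapped to (-pi, pi].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import ShapeError, ValidationError
from .rewards import BodyKinematics, IMUTriplet, wrap_angle

# Full-scale musculoskeletal layout contract (observation/action sizes of the
# 3D human lower-body model with 22 muscles): used by the conditioned-network
# arithmetic and asserted by layout_self_check().
FULL_STATE_DIM = 97
FULL_ACTION_DIM = 22
FIELD_SHAPE = (2, 11, 11)
FIELD_FLAT_DIM = int(np.prod(FIELD_SHAPE))  # 242
FULL_POLICY_INPUT_DIM = FULL_STATE_DIM + FIELD_FLAT_DIM  # 339
FULL_CRITIC_INPUT_DIM = FULL_POLICY_INPUT_DIM + FULL_ACTION_DIM  # 361

CELL_SIZE = 0.5  # m, side of one target-field cell
GRID_N = 11


def layout_self_check() -> dict[str, int]:
    """Recompute and return the full-model layout constants from the grid
    and state/action contracts; raises if the arithmetic is inconsistent."""
    flat = 2 * GRID_N * GRID_N
    policy_in = FULL_STATE_DIM + flat
    critic_in = policy_in + FULL_ACTION_DIM
    if flat != FIELD_FLAT_DIM or policy_in != FULL_POLICY_INPUT_DIM:
        raise ShapeError("layout contract violated")
    if critic_in != FULL_CRITIC_INPUT_DIM:
        raise ShapeError("layout contract violated")
    return {
        "state_dim": FULL_STATE_DIM,
        "action_dim": FULL_ACTION_DIM,
        "field_flat_dim": flat,
        "policy_input_dim": policy_in,
        "critic_input_dim": critic_in,
    }


# ---------------------------------------------------------------------------
# target-velocity field


@dataclass
class TargetVelocityField:
    """2 x 11 x 11 grid of local target velocities (m/s) on 0.5 m cells
    centered on the agent, axis-aligned with the world frame."""

    grid: np.ndarray

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=np.float64)
        if self.grid.shape != FIELD_SHAPE:
            raise ShapeError(f"field shape {self.grid.shape} != {FIELD_SHAPE}")
        if not np.all(np.isfinite(self.grid)):
            raise ValidationError("non-finite target field")

    def flatten(self) -> np.ndarray:
        return self.grid.reshape(-1)

    def at_agent(self) -> np.ndarray:
        """Target velocity of the center cell (the cell under the pelvis)."""
        c = GRID_N // 2
        return self.grid[:, c, c].copy()


def cruise_speed_profile(
    cruise: float = 1.25, stop_radius: float = 0.36, taper_to: float = 0.5
) -> Callable[[float], float]:
    """Speed-magnitude profile: ``cruise`` far from the target, linear taper
    to zero starting ``taper_to`` meters out, exactly zero inside
    ``stop_radius`` (which covers any cell whose center lies in the cell
    containing the target)."""

    def profile(d: float) -> float:
        if d <= stop_radius:
            return 0.0
        return cruise * min(1.0, (d - stop_radius) / (taper_to - stop_radius))

    return profile


def make_target_field(
    agent_pose: np.ndarray,
    target: np.ndarray = np.array([5.0, 0.0]),
    speed_profile: Callable[[float], float] | None = None,
) -> TargetVelocityField:
    """Local target-velocity field around the agent.

    Each cell's vector points from the cell center toward the target with a
    magnitude given by the speed profile of the center-to-target distance.
    """
    target = np.asarray(target, dtype=np.float64)
    pos = np.asarray(agent_pose, dtype=np.float64)[:2]
    if not np.all(np.isfinite(target)):
        raise ValidationError("non-finite target")
    if speed_profile is None:
        speed_profile = cruise_speed_profile()
    half = GRID_N // 2
    offsets = CELL_SIZE * (np.arange(GRID_N) - half)
    cx = pos[0] + offsets[:, None]  # (11, 1) broadcast over columns
    cy = pos[1] + offsets[None, :]
    dx = target[0] - cx
    dy = target[1] - cy + np.zeros_like(cx)
    d = np.hypot(dx, dy)
    mag = np.vectorize(speed_profile, otypes=[np.float64])(d)
    with np.errstate(invalid="ignore", divide="ignore"):
        scale = np.where(d > 0.0, mag / np.maximum(d, 1e-300), 0.0)
    grid = np.stack([dx * scale, dy * scale])
    return TargetVelocityField(grid)


# ---------------------------------------------------------------------------
# pelvis orientation <-> Euler angles (intrinsic Z-X-Y)


def euler_zxy_to_rotation(roll: float, pitch: float, yaw: float) -> Rotation:
    """Rotation from pelvis Z-X-Y Euler angles (yaw, then roll, then pitch)."""
    return Rotation.from_euler("ZXY", [yaw, roll, pitch])


def rotation_to_euler_zxy(rot: Rotation) -> IMUTriplet:
    """Inverse of :func:`euler_zxy_to_rotation`; at the gimbal-degenerate
    orientation (|roll| = pi/2) scipy's convention (yaw absorbs the free
    angle, pitch set to 0) is returned rather than raising."""
    yaw, roll, pitch = rot.as_euler("ZXY")
    return IMUTriplet(roll=wrap_angle(roll), pitch=wrap_angle(pitch), yaw=wrap_angle(yaw))


# ---------------------------------------------------------------------------
# synthetic planar walker


@dataclass
class WalkerParams:
    """Dynamics constants of the synthetic walker.

    Chosen once so that (a) zero excitation produces no displacement and a
    fall within two simulated seconds, and (b) the shipped open-loop gait
    fixture covers 5 m in under 10 s at a natural-looking cadence.
    """

    dt: float = 0.01
    n_muscles: int = 6  # [hip_ext, hip_flex, ankle] x {left, right}
    tau_act: float = 0.05  # s, first-order activation time constant
    thrust_gain: float = 5.2  # m/s^2 per unit stance-leg extensor drive
    ankle_gain: float = 2.0  # m/s^2 per unit stance-leg ankle drive
    drag: float = 2.2  # 1/s, velocity damping
    brake_gain: float = 5.0  # m/s^2 per unit flexor drive (deceleration)
    lat_gain: float = 0.9  # m/s^2 lateral push per unit stance asymmetry
    yaw_gain: float = 0.3  # rad/s per unit left-right drive asymmetry
    step_rate_gain: float = 16.0  # rad/s phase rate per unit mean activation
    contact_margin: float = -0.2  # sin(phase) threshold for foot contact
    roll_amp: float = 0.06  # rad, pelvis roll oscillation at full gait
    pitch_amp: float = 0.04  # rad, pelvis pitch oscillation at full gait
    tau_ang: float = 0.08  # s, orientation tracking time constant
    # slow posture coupling: sustained drive above the neutral level pitches
    # the pelvis (lean), sustained left-right asymmetry rolls it — pelvis
    # orientation is policy-dependent, as in a musculoskeletal model, so an
    # orientation-agnostic controller can and does walk with a tilted pelvis
    lean_gain: float = 0.6  # rad per unit sustained excess drive
    roll_bias_gain: float = 0.4  # rad per unit sustained drive asymmetry
    neutral_drive: float = 0.52  # drive level with zero pitch lean
    tau_posture: float = 0.5  # s, low-pass constant of the posture coupling
    support_gain: float = 1.0  # height recovery per unit mean activation
    height_leak: float = 0.3  # 1/s, passive height decay
    fall_height: float = 0.5  # height proxy below which the walker falls
    pelvis_height: float = 0.92  # m, nominal pelvis height scale
    torso_len: float = 0.62  # m, pelvis-to-head distance
    foot_half_width: float = 0.12  # m, lateral foot offset
    step_len: float = 0.30  # m, fore-aft foot excursion amplitude
    target_radius: float = 0.30  # m, reach tolerance
    max_time: float = 5.0  # s, episode horizon

    def __post_init__(self):
        if self.dt <= 0:
            raise ValidationError("dt must be positive")


@dataclass
class WalkerState:
    """Full internal state of the synthetic walker."""

    x: float = 0.0
    y: float = 0.0
    vx: float = 0.0
    vy: float = 0.0
    roll: float = 0.0
    pitch: float = 0.0
    yaw: float = 0.0
    roll_rate: float = 0.0
    pitch_rate: float = 0.0
    yaw_rate: float = 0.0
    hip_l: float = 0.0
    hip_r: float = 0.0
    hip_l_rate: float = 0.0
    hip_r_rate: float = 0.0
    activations: np.ndarray = field(default_factory=lambda: np.zeros(6))
    phase: float = 0.0
    height: float = 0.92
    drive_lp: float = 0.52  # low-passed mean stance drive
    asym_lp: float = 0.0  # low-passed left-right drive asymmetry
    contact_l: bool = True
    contact_r: bool = True
    time: float = 0.0
    fallen: bool = False

    def copy(self) -> "WalkerState":
        s = WalkerState(**{k: v for k, v in self.__dict__.items() if k != "activations"})
        s.activations = self.activations.copy()
        return s


class SyntheticWalker:
    """Simplified planar biped with muscle-like first-order actuation.

    Six excitation channels in [0, 1]: hip extensor, hip flexor and ankle
    extensor per leg. Stance-leg extensor and ankle drive accelerate the
    pelvis along the heading; flexor drive brakes; left-right drive
    asymmetry pushes laterally and turns the heading (yaw). The stepping
    phase advances at a rate proportional to overall activation, feet
    alternate contact with a short double-stance window, and pelvis roll and
    pitch oscillate with the gait. A height proxy integrates support drive
    against a passive leak; the walker falls when it drops below the fall
    threshold. Fully deterministic given (state, action).
    """

    # observation layout (documented contract for the synthetic walker)
    OBS_LAYOUT = (
        "vx", "vy", "height",
        "roll", "pitch", "yaw",
        "roll_rate", "pitch_rate", "yaw_rate",
        "hip_l", "hip_r", "hip_l_rate", "hip_r_rate",
        "act_0", "act_1", "act_2", "act_3", "act_4", "act_5",
        "contact_l", "contact_r",
        "sin_phase", "cos_phase",
        "vtgt_x", "vtgt_y",
        "to_target_x", "to_target_y",
    )
    OBS_DIM = len(OBS_LAYOUT)  # 27
    ACTION_DIM = 6

    def __init__(
        self,
        params: WalkerParams | None = None,
        target: np.ndarray = np.array([5.0, 0.0]),
        speed_profile: Callable[[float], float] | None = None,
    ):
        self.params = params or WalkerParams()
        self.target = np.asarray(target, dtype=np.float64)
        self.speed_profile = speed_profile or cruise_speed_profile()
        self.state = WalkerState(height=self.params.pelvis_height)

    # -- contract -----------------------------------------------------------

    def reset(self, seed: int | None = None) -> np.ndarray:
        """Reset to the start pose. The walker is deterministic; ``seed`` is
        accepted for contract compatibility and reserved for stochastic
        variants (e.g. randomized targets at difficulty 2)."""
        del seed
        self.state = WalkerState(height=self.params.pelvis_height)
        return self.observe()

    def step(
        self, action: np.ndarray, seed: int | None = None
    ) -> tuple[np.ndarray, BodyKinematics, bool]:
        """Advance one timestep. Returns (observation, kinematics, done)."""
        del seed
        self.state, obs, kin, done = step_walker(
            self.state, np.asarray(action, dtype=np.float64), self
        )
        return obs, kin, done

    # -- helpers ------------------------------------------------------------

    @property
    def field(self) -> TargetVelocityField:
        """Target-velocity field around the current pose (computed on demand)."""
        return make_target_field(
            np.array([self.state.x, self.state.y]),
            self.target,
            self.speed_profile,
        )

    def v_tgt_at_pelvis(self) -> np.ndarray:
        """Local target velocity at the pelvis cell (the center cell's value,
        computed directly: its center is the agent position)."""
        delta = self.target - np.array([self.state.x, self.state.y])
        d = float(np.linalg.norm(delta))
        mag = self.speed_profile(d)
        if mag <= 0.0 or d == 0.0:
            return np.zeros(2)
        return mag * delta / d

    def observe(self) -> np.ndarray:
        s = self.state
        vtgt = self.v_tgt_at_pelvis()
        to_tgt = self.target - np.array([s.x, s.y])
        return np.array(
            [
                s.vx, s.vy, s.height,
                s.roll, s.pitch, s.yaw,
                s.roll_rate, s.pitch_rate, s.yaw_rate,
                s.hip_l, s.hip_r, s.hip_l_rate, s.hip_r_rate,
                *s.activations,
                float(s.contact_l), float(s.contact_r),
                np.sin(s.phase), np.cos(s.phase),
                vtgt[0], vtgt[1],
                to_tgt[0], to_tgt[1],
            ]
        )

    def kinematics(self) -> BodyKinematics:
        """Kinematic summary of the current state for the reward terms."""
        s, p = self.state, self.params
        heading = s.yaw
        cy, sy = np.cos(heading), np.sin(heading)
        fwd = np.array([cy, sy, 0.0])
        left = np.array([-sy, cy, 0.0])
        pelvis = np.array([s.x, s.y, s.height])
        head = pelvis + p.torso_len * np.array(
            [np.sin(s.pitch) * cy, np.sin(s.pitch) * sy, np.cos(s.pitch)]
        ) + p.torso_len * np.sin(s.roll) * left
        foot_l = (
            np.array([s.x, s.y, 0.0])
            + p.step_len * np.sin(s.phase) * fwd
            + p.foot_half_width * left
        )
        foot_r = (
            np.array([s.x, s.y, 0.0])
            - p.step_len * np.sin(s.phase) * fwd
            - p.foot_half_width * left
        )
        in_step = s.contact_l != s.contact_r  # exactly one foot in contact
        return BodyKinematics(
            v_body=np.array([s.vx, s.vy]),
            v_vel=np.array([s.vx, s.vy]),
            v_tgt=self.v_tgt_at_pelvis(),
            r_head=head,
            r_pelvis=pelvis,
            r_left=foot_l,
            r_right=foot_r,
            activations=s.activations.copy(),
            in_step=bool(in_step),
            dt=p.dt,
            fallen=s.fallen,
        )


def observe_imu(state: WalkerState) -> IMUTriplet:
    """Pelvis orientation as wrapped Z-X-Y Euler angles (roll, pitch, yaw)."""
    return IMUTriplet(
        roll=wrap_angle(state.roll),
        pitch=wrap_angle(state.pitch),
        yaw=wrap_angle(state.yaw),
    )


def step_walker(
    state: WalkerState,
    action: np.ndarray,
    walker: SyntheticWalker,
) -> tuple[WalkerState, np.ndarray, BodyKinematics, bool]:
    """Pure single-step transition of the synthetic walker dynamics.

    Deterministic given (state, action); returns the successor state, the
    observation, the kinematic summary used by the reward terms, and the
    done flag (fall or target reached or horizon).
    """
    p = walker.params
    action = np.asarray(action, dtype=np.float64)
    if action.shape != (p.n_muscles,):
        raise ShapeError(f"expected action shape ({p.n_muscles},), got {action.shape}")
    if not np.all(np.isfinite(action)):
        raise ValidationError("non-finite action")
    u = np.clip(action, 0.0, 1.0)

    s = state.copy()
    dt = p.dt

    # first-order muscle activation dynamics
    s.activations = s.activations + dt * (u - s.activations) / p.tau_act
    a = s.activations
    he_l, hf_l, an_l = a[0], a[1], a[2]
    he_r, hf_r, an_r = a[3], a[4], a[5]

    # stepping phase: cadence scales with overall drive
    mean_act = float(np.mean(a))
    s.phase = float(np.mod(s.phase + dt * p.step_rate_gain * mean_act, 2 * np.pi))
    sin_ph = np.sin(s.phase)
    s.contact_l = bool(sin_ph > p.contact_margin)
    s.contact_r = bool(-sin_ph > p.contact_margin)
    c_l, c_r = float(s.contact_l), float(s.contact_r)

    # planar dynamics in the heading frame
    drive_l = (he_l + 0.5 * an_l) * c_l
    drive_r = (he_r + 0.5 * an_r) * c_r
    thrust = p.thrust_gain * 0.5 * (drive_l + drive_r) + p.ankle_gain * 0.5 * (
        an_l * c_l + an_r * c_r
    )
    brake = p.brake_gain * 0.5 * (hf_l + hf_r)
    ax_body = thrust - brake
    ay_body = p.lat_gain * (drive_l - drive_r)
    cyaw, syaw = np.cos(s.yaw), np.sin(s.yaw)
    ax = ax_body * cyaw - ay_body * syaw - p.drag * s.vx
    ay = ax_body * syaw + ay_body * cyaw - p.drag * s.vy
    s.vx += dt * ax
    s.vy += dt * ay
    s.x += dt * s.vx
    s.y += dt * s.vy

    # heading turns with left-right drive asymmetry
    new_yaw_rate = p.yaw_gain * ((he_l + hf_l + an_l) - (he_r + hf_r + an_r))
    s.yaw = wrap_angle(s.yaw + dt * new_yaw_rate)
    s.yaw_rate = new_yaw_rate

    # slow posture coupling (low-passed drive level and asymmetry)
    s.drive_lp += dt * (0.5 * (drive_l + drive_r) - s.drive_lp) / p.tau_posture
    s.asym_lp += dt * ((drive_l - drive_r) - s.asym_lp) / p.tau_posture

    # pelvis roll/pitch track gait-locked oscillation targets plus the
    # posture lean/bias induced by the sustained drive pattern
    speed_factor = min(1.0, float(np.hypot(s.vx, s.vy)) / 1.0)
    roll_target = (
        p.roll_amp * sin_ph * speed_factor + p.roll_bias_gain * s.asym_lp
    )
    pitch_target = (
        p.pitch_amp * np.sin(2.0 * s.phase) * speed_factor
        - p.lean_gain * (s.drive_lp - p.neutral_drive)
    )
    new_roll = s.roll + dt * (roll_target - s.roll) / p.tau_ang
    new_pitch = s.pitch + dt * (pitch_target - s.pitch) / p.tau_ang
    s.roll_rate = (new_roll - s.roll) / dt
    s.pitch_rate = (new_pitch - s.pitch) / dt
    s.roll, s.pitch = new_roll, new_pitch

    # hip angles are kinematic readouts of the stepping phase
    hip_amp = 0.4
    new_hip_l = hip_amp * sin_ph * speed_factor
    new_hip_r = -hip_amp * sin_ph * speed_factor
    s.hip_l_rate = (new_hip_l - s.hip_l) / dt
    s.hip_r_rate = (new_hip_r - s.hip_r) / dt
    s.hip_l, s.hip_r = new_hip_l, new_hip_r

    # height proxy: support drive against passive leak
    s.height += dt * p.pelvis_height * (
        p.support_gain * mean_act - p.height_leak
    )
    s.height = min(s.height, p.pelvis_height)
    s.time += dt
    s.fallen = s.height < p.fall_height

    walker.state = s

    dist = float(np.hypot(walker.target[0] - s.x, walker.target[1] - s.y))
    reached = dist < p.target_radius
    done = bool(s.fallen or reached or s.time >= p.max_time - 1e-12)

    obs = walker.observe()
    kin = walker.kinematics()
    return s, obs, kin, done


def reference_gait_excitation(phase: float) -> np.ndarray:
    """Hand-tuned open-loop excitation pattern that walks the synthetic
    walker in a straight line (>= 5 m in <= 10 s from standstill).

    Stance-side hip extensor and ankle fire during their half cycle, the
    swing-side flexor lifts lightly; the pattern is left-right symmetric so
    the heading stays straight.
    """
    s = np.sin(phase)
    stance_l = max(0.0, s)
    stance_r = max(0.0, -s)
    return np.array(
        [
            0.35 + 0.55 * stance_l,  # hip extensor L
            0.05 + 0.10 * stance_r,  # hip flexor L (swing lift)
            0.30 + 0.50 * stance_l,  # ankle L
            0.35 + 0.55 * stance_r,  # hip extensor R
            0.05 + 0.10 * stance_l,  # hip flexor R
            0.30 + 0.50 * stance_r,  # ankle R
        ]
    )


# ---------------------------------------------------------------------------
# synthetic reference-IMU generator


@dataclass
class IMUReferenceTrace:
    """Time-aligned roll/pitch/yaw reference sequence at a uniform period.

    ``angles`` has shape (n_samples, 3) in radians, column order
    (roll, pitch, yaw); ``dt`` is the sampling period in seconds.
    """

    dt: float
    angles: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.angles = np.asarray(self.angles, dtype=np.float64)
        if self.angles.ndim != 2 or self.angles.shape[1] != 3:
            raise ShapeError(f"expected (n, 3) angles, got {self.angles.shape}")
        if self.dt <= 0:
            raise ValidationError("sampling period must be positive")
        if not np.all(np.isfinite(self.angles)):
            raise ValidationError("non-finite reference angles")

    def __len__(self) -> int:
        return self.angles.shape[0]

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self)) * self.dt

    def triplet_at(self, index: int) -> IMUTriplet:
        r, p, y = self.angles[index]
        return IMUTriplet(roll=r, pitch=p, yaw=y)


# Default study conditions for the synthetic reference: a comfortable-speed
# straight walk sampled at 100 Hz for 5 s. Gait cycle ~1.1 s; pelvis roll /
# pitch / yaw oscillation amplitudes of a few degrees, no heading drift,
# small sensor noise.
DEFAULT_GAIT_PERIOD = 1.1  # s
DEFAULT_AMPLITUDES = (0.06, 0.04, 0.05)  # rad (roll, pitch, yaw)
DEFAULT_PHASES = (0.0, np.pi / 2.0, np.pi)  # rad
DEFAULT_NOISE = 0.005  # rad, additive Gaussian sd


def generate_reference_imu(
    gait_period: float = DEFAULT_GAIT_PERIOD,
    amplitudes: tuple[float, float, float] = DEFAULT_AMPLITUDES,
    phases: tuple[float, float, float] = DEFAULT_PHASES,
    drift: tuple[float, float, float] = (0.0, 0.0, 0.0),
    noise: float = DEFAULT_NOISE,
    duration: float = 5.0,
    dt: float = 0.01,
    seed: int | None = 0,
) -> IMUReferenceTrace:
    """Synthetic pelvis-IMU reference trace for a periodic straight walk.

    Per axis: a sinusoid at the gait frequency (pitch at twice the gait
    frequency, reflecting its two peaks per stride) plus a linear drift and
    seeded additive Gaussian noise. Emulates a pelvis-mounted IMU recording
    of a short straight walk; it does not model sensor bias instability,
    magnetometer disturbance, or stride-to-stride variability.
    """
    if gait_period <= 0:
        raise ValidationError("gait period must be positive")
    if dt <= 0 or duration < dt:
        raise ValidationError("need dt > 0 and duration >= dt")
    n = int(round(duration / dt))
    t = np.arange(n) * dt
    omega = 2.0 * np.pi / gait_period
    freq_mult = (1.0, 2.0, 1.0)  # pitch oscillates twice per gait cycle
    rng = np.random.default_rng(seed)
    angles = np.empty((n, 3))
    for ax in range(3):
        angles[:, ax] = (
            amplitudes[ax] * np.sin(freq_mult[ax] * omega * t + phases[ax])
            + drift[ax] * t
        )
    if noise > 0:
        angles += rng.normal(0.0, noise, size=angles.shape)
    meta = {
        "gait_period_s": gait_period,
        "amplitudes_rad": tuple(amplitudes),
        "phases_rad": tuple(phases),
        "drift_rad_per_s": tuple(drift),
        "noise_rad": noise,
        "seed": seed,
    }
    return IMUReferenceTrace(dt=dt, angles=angles, metadata=meta)
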