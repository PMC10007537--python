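"""Stage-two policy distillation into target-velocity-conditioned networks.

The stage-one teacher pi^t(a|s) and Q^t(s, a) are frozen; a student
pi^s(a|s, v) and Q^s(s, v, a) — identical architecture but with the
flattened 2x11x11 target-velocity field appended to the input — is trained
offline on observations replayed from the saved stage-one experience:

    J_pi^s = E_s E_v [ KL( pi^s(.|s, v) || pi^t(.|s) ) ]
    J_Q^s  = E_s E_v [ ( Q^s(s, v, a~pi^s) - Q^t(s, a~pi^t) )^2 ]

with v perturbed per element by zero-mean Gaussian noise of variance 0.1.
The KL between the two factorized Gaussians (pre-squash; the squashing map
is shared, so the divergence is unchanged) is evaluated in closed form,
which also gives exact gradients for the student's mean and log-variance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .environment import FIELD_FLAT_DIM, TargetVelocityField
from .errors import ShapeError
from .nn import Adam
from .rewards import RewardWeights
from .sac import GaussianPolicy, MultiHeadCritic

V_NOISE_VARIANCE = 0.1  # per-entry variance of the target-velocity jitter


def condition_inputs(state: np.ndarray, field: TargetVelocityField | np.ndarray) -> np.ndarray:
    """Concatenate [state || flattened field], state first.

    The field flattens in C order: axis (x then y), then grid row, then
    grid column — the fixed documented layout for conditioned networks.
    """
    state = np.asarray(state, dtype=np.float64)
    flat = (
        field.flatten()
        if isinstance(field, TargetVelocityField)
        else np.asarray(field, dtype=np.float64).reshape(-1)
    )
    if flat.shape[0] != FIELD_FLAT_DIM:
        raise ShapeError(
            f"expected flattened field length {FIELD_FLAT_DIM}, got {flat.shape[0]}"
        )
    if state.ndim == 1:
        return np.concatenate([state, flat])
    return np.concatenate(
        [state, np.broadcast_to(flat, (state.shape[0], flat.shape[0]))], axis=1
    )


@dataclass
class ConditionedNetworks:
    """Student policy/critic conditioned on the target-velocity field."""

    policy: GaussianPolicy
    critic: MultiHeadCritic
    v_dim: int = FIELD_FLAT_DIM

    @classmethod
    def fresh(
        cls,
        obs_dim: int,
        act_dim: int,
        n_heads: int,
        hidden: tuple[int, ...] = (1024, 1024, 1024, 1024),
        v_dim: int = FIELD_FLAT_DIM,
        rng: np.random.Generator | None = None,
    ) -> "ConditionedNetworks":
        rng = rng or np.random.default_rng(0)
        return cls(
            policy=GaussianPolicy(obs_dim + v_dim, act_dim, hidden, rng=rng),
            critic=MultiHeadCritic(obs_dim + v_dim, act_dim, n_heads, hidden, rng=rng),
            v_dim=v_dim,
        )

    @classmethod
    def from_teacher(
        cls,
        teacher_policy: GaussianPolicy,
        teacher_critic: MultiHeadCritic,
        v_dim: int = FIELD_FLAT_DIM,
    ) -> "ConditionedNetworks":
        """Student that initially ignores v and reproduces the teacher
        exactly: teacher weights are embedded and the first-layer rows for
        the appended v entries start at zero."""
        sp = GaussianPolicy(
            teacher_policy.obs_dim + v_dim,
            teacher_policy.act_dim,
            tuple(teacher_policy.mlp.sizes[1:-1]),
        )
        for k, w in teacher_policy.params.items():
            if k == "W0":
                sp.params["W0"][...] = 0.0
                sp.params["W0"][: w.shape[0]] = w
            else:
                sp.params[k][...] = w
        sc = MultiHeadCritic(
            teacher_critic.obs_dim + v_dim,
            teacher_critic.act_dim,
            teacher_critic.n_heads,
            tuple(teacher_critic.mlp.sizes[1:-1]),
        )
        for k, w in teacher_critic.params.items():
            if k == "W0":
                sc.params["W0"][...] = 0.0
                # critic input order is [state || v || action]
                sd = teacher_critic.obs_dim
                sc.params["W0"][:sd] = w[:sd]
                sc.params["W0"][sd + v_dim :] = w[sd:]
            else:
                sc.params[k][...] = w
        return cls(policy=sp, critic=sc, v_dim=v_dim)


def gaussian_kl(
    mu_s: np.ndarray, log_std_s: np.ndarray, mu_t: np.ndarray, log_std_t: np.ndarray
) -> np.ndarray:
    """Per-sample KL(student || teacher) between factorized Gaussians."""
    var_s = np.exp(2.0 * log_std_s)
    var_t = np.exp(2.0 * log_std_t)
    per_dim = (
        log_std_t - log_std_s + (var_s + (mu_s - mu_t) ** 2) / (2.0 * var_t) - 0.5
    )
    return per_dim.sum(axis=1)


def distill_losses(
    teacher_policy: GaussianPolicy,
    teacher_critic: MultiHeadCritic,
    student: ConditionedNetworks,
    batch_obs: np.ndarray,
    field: TargetVelocityField | np.ndarray,
    weights: RewardWeights,
    v_noise_seed: int = 0,
    v_noise_variance: float = V_NOISE_VARIANCE,
    v_noise: np.ndarray | None = None,
    action_eps: np.ndarray | None = None,
    return_grads: bool = False,
):
    """Distillation objectives (and optionally student gradients).

    Returns a dict with ``J_pi_s`` (mean closed-form Gaussian KL) and
    ``J_Q_s`` (mean squared error between the weighted-scalar student and
    teacher critic values at their own policies' sampled actions).
    """
    obs = np.atleast_2d(np.asarray(batch_obs, dtype=np.float64))
    if obs.shape[1] != teacher_policy.obs_dim:
        raise ShapeError(
            f"batch obs dim {obs.shape[1]} != teacher obs dim "
            f"{teacher_policy.obs_dim}"
        )
    if teacher_policy.act_dim != student.policy.act_dim:
        raise ShapeError("teacher/student action dimension mismatch")
    rng = np.random.default_rng(v_noise_seed)
    flat = (
        field.flatten()
        if isinstance(field, TargetVelocityField)
        else np.asarray(field).reshape(-1)
    )
    B = obs.shape[0]
    if v_noise is None:
        v_noise = rng.normal(
            0.0, np.sqrt(v_noise_variance), size=(B, flat.shape[0])
        )
    v = flat[None, :] + v_noise
    sv = np.concatenate([obs, v], axis=1)

    # policy KL (closed form)
    mu_t, log_std_t, _ = teacher_policy.forward(obs)
    cache_p: list = []
    mu_s, log_std_s, dclamp = _student_policy_forward(student.policy, sv, cache_p)
    kl = gaussian_kl(mu_s, log_std_s, mu_t, log_std_t)
    j_pi_s = float(kl.mean())

    # critic MSE at each network's own sampled action; common random numbers
    # (one shared pre-squash noise draw) keep the comparison low-variance and
    # make exact self-distillation measure exactly zero
    if action_eps is None:
        action_eps = np.random.default_rng(v_noise_seed + 1).standard_normal(
            (B, teacher_policy.act_dim)
        )
    a_t, _, _ = teacher_policy.sample(obs, eps=action_eps)
    a_s, _, _ = student.policy.sample(sv, eps=action_eps)
    q_t = teacher_critic.q_values(obs, a_t) @ weights.w
    cache_c: list = []
    sva = student.critic.q_values(sv, a_s, cache_c)
    q_s = sva @ weights.w
    resid = q_s - q_t
    j_q_s = float(np.mean(resid**2))

    out = {"J_pi_s": j_pi_s, "J_Q_s": j_q_s}
    if return_grads:
        var_t = np.exp(2.0 * log_std_t)
        d_mu = (mu_s - mu_t) / var_t / B
        d_ls = (np.exp(2.0 * log_std_s) / var_t - 1.0) / B
        dout = np.concatenate([d_mu, d_ls * dclamp], axis=1)
        pgrads, _ = student.policy.mlp.backward(dout, cache_p)
        dq = (2.0 * resid[:, None] * weights.w[None, :]) / B
        cgrads, _ = student.critic.mlp.backward(dq, cache_c)
        out["policy_grads"] = pgrads
        out["critic_grads"] = cgrads
    return out


def _student_policy_forward(policy: GaussianPolicy, x: np.ndarray, cache: list):
    out = policy.mlp.forward(x, cache)
    return policy._heads(out)


def distill_stage_two(
    teacher_policy: GaussianPolicy,
    teacher_critic: MultiHeadCritic,
    replay,
    field: TargetVelocityField,
    weights: RewardWeights,
    hidden: tuple[int, ...] = (1024, 1024, 1024, 1024),
    steps: int = 200,
    batch_size: int = 128,
    lr: float = 1e-4,
    seed: int = 0,
    init_from_teacher: bool = False,
) -> tuple[ConditionedNetworks, list[dict]]:
    """Offline stage-two training on the saved stage-one replay.

    The teacher parameters are never touched; only the student is updated.
    Returns the trained student and the per-step loss history.
    """
    ss = np.random.SeedSequence(seed)
    init_seed, sample_seed, noise_seed0 = (
        int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(3)
    )
    if init_from_teacher:
        student = ConditionedNetworks.from_teacher(
            teacher_policy, teacher_critic
        )
    else:
        student = ConditionedNetworks.fresh(
            teacher_policy.obs_dim,
            teacher_policy.act_dim,
            teacher_critic.n_heads,
            hidden,
            rng=np.random.default_rng(init_seed),
        )
    opt_p = Adam(student.policy.params, lr)
    opt_c = Adam(student.critic.params, lr)
    rng = np.random.default_rng(sample_seed)
    history = []
    for step in range(steps):
        _, segments, _ = replay.sample(
            max(1, batch_size // replay.L), step, rng
        )
        obs = np.array(
            [tr.observation for seg in segments
             for tr, real in zip(seg.transitions, seg.mask) if real]
        )[:batch_size]
        res = distill_losses(
            teacher_policy, teacher_critic, student, obs, field, weights,
            v_noise_seed=noise_seed0 + step, return_grads=True,
        )
        opt_p.step(res["policy_grads"])
        opt_c.step(res["critic_grads"])
        history.append({"J_pi_s": res["J_pi_s"], "J_Q_s": res["J_Q_s"]})
    return student, history
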