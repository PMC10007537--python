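"""Soft Actor-Critic with one Q head per reward component.

The critic outputs a vector of per-component Q values; the vector of critic
losses is optimized head by head, while the actor maximizes the weighted
scalarization

    Q(s, a) = sum_i w_i * Q_i(s, a)

so reward terms can be added or removed ("head surgery") without
interfering with the others. Bootstrapped targets use n-step returns and
invertible value rescaling; the entropy temperature alpha is adapted toward
a target entropy.

The stochastic policy is a factorized Gaussian over pre-squash actions,
squashed to the muscle-excitation box [0, 1]^A by a = (tanh(u) + 1) / 2,
with the exact change-of-variables correction in the log density.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np

from .errors import ContractError, ShapeError, ValidationError
from .nn import MLP, Adam, polyak_update
from .rewards import N_COMPONENTS, REWARD_COMPONENTS, RewardWeights

LOG_STD_MIN = -5.0
LOG_STD_MAX = 2.0
_LOG_2PI = np.log(2.0 * np.pi)


# ---------------------------------------------------------------------------
# invertible value rescaling


def value_rescale(x, eps: float = 1e-3):
    """h(x) = sign(x) * (sqrt(|x| + 1) - 1) + eps * x (compresses targets)."""
    x = np.asarray(x, dtype=np.float64)
    out = np.sign(x) * (np.sqrt(np.abs(x) + 1.0) - 1.0) + eps * x
    return out if out.ndim else float(out)


def value_rescale_inverse(y, eps: float = 1e-3):
    """Closed-form inverse of :func:`value_rescale`."""
    y = np.asarray(y, dtype=np.float64)
    num = np.sqrt(1.0 + 4.0 * eps * (np.abs(y) + 1.0 + eps)) - 1.0
    out = np.sign(y) * ((num / (2.0 * eps)) ** 2 - 1.0)
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# n-step targets


def n_step_target(
    rewards: np.ndarray,
    bootstrap: np.ndarray,
    gamma: float,
    n: int,
    terminated: bool = False,
    rescale: bool = True,
) -> np.ndarray:
    """Per-head n-step return target.

    ``rewards`` is an (m, H) array of the reward vectors at t .. t+m-1;
    the bootstrap is the per-head value at t+n (stored on the compressed
    scale when ``rescale`` is on, so it is decompressed before discounting
    and the final target re-compressed). Termination inside the window
    truncates both the sum and the bootstrap.
    """
    rewards = np.atleast_2d(np.asarray(rewards, dtype=np.float64))
    bootstrap = np.asarray(bootstrap, dtype=np.float64)
    if not 0.0 < gamma <= 1.0:
        raise ContractError(f"gamma must be in (0, 1], got {gamma}")
    if n < 1:
        raise ContractError(f"n must be >= 1, got {n}")
    m = rewards.shape[0]
    if m < n and not terminated:
        raise ContractError(
            f"n = {n} exceeds available horizon {m} without termination"
        )
    k = min(n, m)
    discounts = gamma ** np.arange(k)
    raw = discounts @ rewards[:k]
    if not terminated:
        boot = value_rescale_inverse(bootstrap) if rescale else bootstrap
        raw = raw + gamma**k * boot
    return value_rescale(raw) if rescale else raw


# ---------------------------------------------------------------------------
# policy


class GaussianPolicy:
    """Squashed factorized-Gaussian policy network.

    An MLP maps the observation to 2A outputs: per-dimension mean and a raw
    log-standard-deviation that is smoothly clamped to
    [LOG_STD_MIN, LOG_STD_MAX] (tanh reparametrization keeps the gradient
    alive at the clamp edges).
    """

    def __init__(
        self,
        obs_dim: int,
        act_dim: int,
        hidden: tuple[int, ...] = (256, 256, 256, 256),
        rng: np.random.Generator | None = None,
    ):
        self.obs_dim = obs_dim
        self.act_dim = act_dim
        self.mlp = MLP(
            [obs_dim, *hidden, 2 * act_dim], hidden_activation="elu", rng=rng
        )

    @property
    def params(self) -> dict[str, np.ndarray]:
        return self.mlp.params

    def _heads(self, out: np.ndarray):
        mu = out[:, : self.act_dim]
        raw = out[:, self.act_dim :]
        t = np.tanh(raw)
        log_std = LOG_STD_MIN + 0.5 * (LOG_STD_MAX - LOG_STD_MIN) * (t + 1.0)
        dlog_std_draw = 0.5 * (LOG_STD_MAX - LOG_STD_MIN) * (1.0 - t * t)
        return mu, log_std, dlog_std_draw

    def forward(self, obs: np.ndarray, cache: list | None = None):
        out = self.mlp.forward(obs, cache)
        return self._heads(out)

    def sample(
        self,
        obs: np.ndarray,
        rng: np.random.Generator | None = None,
        eps: np.ndarray | None = None,
        deterministic: bool = False,
        cache: list | None = None,
    ):
        """Reparametrized sample.

        Returns ``(action, log_prob, aux)`` where ``aux`` carries the
        intermediate tensors needed for the hand-written backward pass.
        """
        obs = np.atleast_2d(np.asarray(obs, dtype=np.float64))
        if obs.shape[1] != self.obs_dim:
            raise ShapeError(f"expected obs dim {self.obs_dim}, got {obs.shape[1]}")
        mu, log_std, dclamp = self.forward(obs, cache)
        std = np.exp(log_std)
        if deterministic:
            eps = np.zeros_like(mu)
        elif eps is None:
            if rng is None:
                rng = np.random.default_rng(0)
            eps = rng.standard_normal(mu.shape)
        u = mu + std * eps
        tanh_u = np.tanh(u)
        action = 0.5 * (tanh_u + 1.0)
        # log N(u; mu, std) - sum log |da/du|, da/du = 0.5 (1 - tanh(u)^2)
        log_gauss = -0.5 * eps**2 - log_std - 0.5 * _LOG_2PI
        log_det = np.log(0.5 * (1.0 - tanh_u**2) + 1e-12)
        log_prob = (log_gauss - log_det).sum(axis=1)
        aux = {
            "mu": mu, "log_std": log_std, "std": std, "eps": eps,
            "u": u, "tanh_u": tanh_u, "dclamp": dclamp,
        }
        return action, log_prob, aux

    def backward(
        self,
        d_mu: np.ndarray,
        d_log_std: np.ndarray,
        aux: dict,
        cache: list,
    ) -> dict[str, np.ndarray]:
        """Backpropagate per-sample gradients w.r.t. (mu, log_std) into the
        network parameters."""
        dout = np.concatenate([d_mu, d_log_std * aux["dclamp"]], axis=1)
        grads, _ = self.mlp.backward(dout, cache)
        return grads

    def copy(self) -> "GaussianPolicy":
        clone = GaussianPolicy.__new__(GaussianPolicy)
        clone.obs_dim = self.obs_dim
        clone.act_dim = self.act_dim
        clone.mlp = self.mlp.copy()
        return clone


def sample_action(
    policy: GaussianPolicy, obs: np.ndarray, seed: int | None = None
):
    """Draw one squashed action and its log density; reproducible per seed."""
    rng = np.random.default_rng(seed)
    action, log_prob, _ = policy.sample(np.atleast_2d(obs), rng=rng)
    return action[0], float(log_prob[0])


# ---------------------------------------------------------------------------
# critic


class MultiHeadCritic:
    """State-action value network with one output head per reward component."""

    def __init__(
        self,
        obs_dim: int,
        act_dim: int,
        n_heads: int = N_COMPONENTS,
        hidden: tuple[int, ...] = (256, 256, 256, 256),
        rng: np.random.Generator | None = None,
    ):
        self.obs_dim = obs_dim
        self.act_dim = act_dim
        self.n_heads = n_heads
        self.mlp = MLP(
            [obs_dim + act_dim, *hidden, n_heads], hidden_activation="relu", rng=rng
        )

    @property
    def params(self) -> dict[str, np.ndarray]:
        return self.mlp.params

    def q_values(
        self, obs: np.ndarray, action: np.ndarray, cache: list | None = None
    ) -> np.ndarray:
        obs = np.atleast_2d(np.asarray(obs, dtype=np.float64))
        action = np.atleast_2d(np.asarray(action, dtype=np.float64))
        x = np.concatenate([obs, action], axis=1)
        return self.mlp.forward(x, cache)

    def dq_daction(
        self, dout: np.ndarray, cache: list
    ) -> tuple[dict[str, np.ndarray], np.ndarray]:
        """Backward pass returning (param grads, gradient w.r.t. action)."""
        grads, dx = self.mlp.backward(dout, cache)
        return grads, dx[:, self.obs_dim :]

    def copy(self) -> "MultiHeadCritic":
        clone = MultiHeadCritic.__new__(MultiHeadCritic)
        clone.obs_dim = self.obs_dim
        clone.act_dim = self.act_dim
        clone.n_heads = self.n_heads
        clone.mlp = self.mlp.copy()
        return clone


def q_scalar(
    critic: MultiHeadCritic,
    obs: np.ndarray,
    action: np.ndarray,
    weights: RewardWeights | np.ndarray,
) -> np.ndarray:
    """Weighted scalarization sum_i w_i * Q_i(s, a)."""
    w = weights.w if isinstance(weights, RewardWeights) else np.asarray(weights)
    if w.shape != (critic.n_heads,):
        raise ShapeError(
            f"weights length {w.shape} != head count {critic.n_heads}"
        )
    q = critic.q_values(obs, action)
    return q @ w


def head_surgery(
    critic: MultiHeadCritic,
    mode: str,
    index: int | None = None,
    weights: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[MultiHeadCritic, np.ndarray | None]:
    """Add or remove a critic head without touching the other heads.

    ``remove`` zeroes the head's output-layer column and bias (and its
    scalarization weight, if a weight vector is passed); ``add`` appends one
    freshly initialized head (and a unit weight). Returns the modified copy
    and the updated weight vector.
    """
    last = critic.mlp.n_layers - 1
    new = critic.copy()
    w = None if weights is None else np.asarray(weights, dtype=np.float64).copy()
    if mode == "remove":
        if index is None or not 0 <= index < critic.n_heads:
            raise ContractError(f"head index {index} out of range")
        new.mlp.params[f"W{last}"][:, index] = 0.0
        new.mlp.params[f"b{last}"][index] = 0.0
        if w is not None:
            w[index] = 0.0
    elif mode == "add":
        rng = rng or np.random.default_rng(0)
        W = new.mlp.params[f"W{last}"]
        col = rng.standard_normal((W.shape[0], 1)) * np.sqrt(2.0 / W.shape[0])
        new.mlp.params[f"W{last}"] = np.concatenate([W, col], axis=1)
        new.mlp.params[f"b{last}"] = np.concatenate(
            [new.mlp.params[f"b{last}"], np.zeros(1)]
        )
        new.n_heads += 1
        new.mlp.sizes[-1] += 1
        if w is not None:
            w = np.concatenate([w, np.ones(1)])
    else:
        raise ContractError(f"unknown surgery mode {mode!r}")
    return new, w


# ---------------------------------------------------------------------------
# temperature


@dataclass
class TemperatureState:
    """Learned entropy temperature and its target entropy."""

    log_alpha: np.ndarray = dc_field(default_factory=lambda: np.array([np.log(0.1)]))
    target_entropy: float = -1.0

    @property
    def alpha(self) -> float:
        return float(np.exp(self.log_alpha[0]))


# ---------------------------------------------------------------------------
# batches and losses


@dataclass
class TrainBatch:
    """Flattened n-step training batch.

    ``rewards`` holds the discounted n-step reward-vector sums, ``next_obs``
    the observation at the bootstrap point, ``discount`` the remaining
    gamma^k product (zero after termination), ``weights`` the importance
    weights, and ``seg_index`` maps each element back to its source segment.
    """

    obs: np.ndarray
    act: np.ndarray
    rewards: np.ndarray
    next_obs: np.ndarray
    done: np.ndarray
    discount: np.ndarray
    weights: np.ndarray
    seg_index: np.ndarray

    def __post_init__(self):
        n = self.obs.shape[0]
        for name in ("act", "rewards", "next_obs", "done", "discount",
                     "weights", "seg_index"):
            if getattr(self, name).shape[0] != n:
                raise ShapeError(f"batch field {name} length mismatch")

    def __len__(self) -> int:
        return self.obs.shape[0]

    def permuted(self, perm: np.ndarray) -> "TrainBatch":
        return TrainBatch(
            obs=self.obs[perm], act=self.act[perm], rewards=self.rewards[perm],
            next_obs=self.next_obs[perm], done=self.done[perm],
            discount=self.discount[perm], weights=self.weights[perm],
            seg_index=self.seg_index[perm],
        )


def build_batch_from_segments(
    segments, is_weights: np.ndarray, gamma: float, n_step: int, rescale: bool = True
) -> TrainBatch:
    """Unroll segments into per-position n-step elements.

    For each valid position the n-step window is truncated at the segment
    end (or at termination); the stored discount is gamma^k with k the
    actual window length, zeroed when the window ends in a terminal step.
    """
    del rescale  # targets are (de)compressed at loss time
    obs, act, rew, nxt, done, disc, w, seg_idx = [], [], [], [], [], [], [], []
    for si, seg in enumerate(segments):
        trs = seg.transitions
        n_valid = seg.n_valid
        for t in range(n_valid):
            k_max = min(n_step, n_valid - t)
            r_sum = np.zeros(N_COMPONENTS)
            g = 1.0
            terminated = False
            k_used = 0
            for k in range(k_max):
                tr = trs[t + k]
                r_sum += g * tr.reward
                g *= gamma
                k_used = k + 1
                if tr.done:
                    terminated = True
                    break
            last = trs[t + k_used - 1]
            obs.append(trs[t].observation)
            act.append(trs[t].action)
            rew.append(r_sum)
            nxt.append(last.next_observation)
            done.append(terminated)
            disc.append(0.0 if terminated else g)
            w.append(is_weights[si])
            seg_idx.append(si)
    return TrainBatch(
        obs=np.array(obs), act=np.array(act), rewards=np.array(rew),
        next_obs=np.array(nxt), done=np.array(done, dtype=bool),
        discount=np.array(disc), weights=np.array(w),
        seg_index=np.array(seg_idx, dtype=int),
    )


def critic_targets(
    batch: TrainBatch,
    policy: GaussianPolicy,
    target_critics: list[MultiHeadCritic],
    temp: TemperatureState,
    rng: np.random.Generator,
    rescale: bool = True,
    entropy_in_bootstrap: bool = False,
) -> np.ndarray:
    """Per-head bootstrapped targets y (B, H) on the compressed scale."""
    a_next, log_prob_next, _ = policy.sample(batch.next_obs, rng=rng)
    qs = [c.q_values(batch.next_obs, a_next) for c in target_critics]
    q_next = np.minimum.reduce(qs) if len(qs) > 1 else qs[0]
    if rescale:
        q_next = value_rescale_inverse(q_next)
    if entropy_in_bootstrap:
        q_next = q_next - temp.alpha * log_prob_next[:, None] / q_next.shape[1]
    raw = batch.rewards + batch.discount[:, None] * q_next
    return value_rescale(raw) if rescale else raw


def critic_loss_and_grads(
    batch: TrainBatch,
    critic: MultiHeadCritic,
    targets: np.ndarray,
) -> tuple[np.ndarray, dict[str, np.ndarray], np.ndarray]:
    """Importance-weighted squared error per head.

    Returns (per-head loss vector, parameter grads, per-sample scalar TD
    residual matrix (B, H) for priority updates).
    """
    cache: list = []
    q = critic.q_values(batch.obs, batch.act, cache)
    resid = q - targets
    wv = batch.weights[:, None]
    losses = 0.5 * np.mean(wv * resid**2, axis=0)
    dout = wv * resid / len(batch)
    grads, _ = critic.mlp.backward(dout, cache)
    if not np.all(np.isfinite(losses)):
        raise ValidationError(f"non-finite critic loss: {losses}")
    return losses, grads, resid


def actor_loss_and_grads(
    batch: TrainBatch,
    policy: GaussianPolicy,
    critics: list[MultiHeadCritic],
    temp: TemperatureState,
    weights: RewardWeights,
    rng: np.random.Generator | None = None,
    eps: np.ndarray | None = None,
) -> tuple[float, dict[str, np.ndarray], np.ndarray]:
    """J_pi = E[alpha * log pi(a|s) - Q_scalar(s, a)] and its policy grads.

    Uses the reparametrization trick: the gradient flows through the sampled
    action into the scalarized (clipped-twin minimum) critic. Returns
    (J_pi, grads, per-sample log_prob) — log_prob feeds the temperature loss.
    """
    B = len(batch)
    cache: list = []
    action, log_prob, aux = policy.sample(batch.obs, rng=rng, eps=eps, cache=cache)
    w = weights.w
    caches = [[] for _ in critics]
    q_heads = [c.q_values(batch.obs, action, cc) for c, cc in zip(critics, caches)]
    q_scalars = [qh @ w for qh in q_heads]
    if len(critics) > 1:
        stacked = np.stack(q_scalars, axis=0)
        which = np.argmin(stacked, axis=0)
        q_min = stacked[which, np.arange(B)]
    else:
        which = np.zeros(B, dtype=int)
        q_min = q_scalars[0]
    alpha = temp.alpha
    j_pi = float(np.mean(alpha * log_prob - q_min))
    if not np.isfinite(j_pi):
        raise ValidationError(f"non-finite actor loss {j_pi}")

    # dQ/da through the per-sample argmin critic
    dq_da = np.zeros_like(action)
    for ci, (c, cc) in enumerate(zip(critics, caches)):
        sel = which == ci
        if not np.any(sel):
            continue
        dout = np.zeros((B, c.n_heads))
        dout[sel] = w
        _, da = c.dq_daction(dout, cc)
        dq_da[sel] = da[sel]

    tanh_u = aux["tanh_u"]
    std = aux["std"]
    epsv = aux["eps"]
    da_du = 0.5 * (1.0 - tanh_u**2)
    # d log_prob: d/dmu = 2*tanh(u); d/dlog_std = -1 + 2*tanh(u)*eps*std
    dlp_dmu = 2.0 * tanh_u
    dlp_dls = -1.0 + 2.0 * tanh_u * epsv * std
    d_mu = (alpha * dlp_dmu - dq_da * da_du) / B
    d_ls = (alpha * dlp_dls - dq_da * da_du * epsv * std) / B
    grads = policy.backward(d_mu, d_ls, aux, cache)
    return j_pi, grads, log_prob


def temperature_loss_and_grad(
    log_prob: np.ndarray, temp: TemperatureState
) -> tuple[float, np.ndarray]:
    """J(alpha) = E[-alpha log pi - alpha H_bar]; gradient w.r.t. log alpha."""
    alpha = temp.alpha
    j_alpha = float(np.mean(-alpha * log_prob - alpha * temp.target_entropy))
    grad = np.array([-alpha * float(np.mean(log_prob + temp.target_entropy))])
    return j_alpha, grad


def sac_losses(
    batch: TrainBatch,
    policy: GaussianPolicy,
    critics: list[MultiHeadCritic],
    target_critics: list[MultiHeadCritic],
    temp: TemperatureState,
    weights: RewardWeights,
    gamma: float = 0.99,
    rescale: bool = True,
    seed: int = 0,
    eps: np.ndarray | None = None,
) -> dict:
    """Evaluate the three SAC objectives on a frozen batch (no updates)."""
    del gamma  # discounting is folded into the batch at construction
    rng = np.random.default_rng(seed)
    targets = critic_targets(batch, policy, target_critics, temp, rng, rescale)
    j_q = []
    for c in critics:
        losses, _, _ = critic_loss_and_grads(batch, c, targets)
        j_q.append(losses)
    j_pi, _, log_prob = actor_loss_and_grads(
        batch, policy, critics, temp, weights,
        rng=np.random.default_rng(seed + 1), eps=eps,
    )
    j_alpha, _ = temperature_loss_and_grad(log_prob, temp)
    return {"J_pi": j_pi, "J_Q": j_q, "J_alpha": j_alpha}


# ---------------------------------------------------------------------------
# agent


@dataclass
class SACConfig:
    """Hyperparameters of the multivariate SAC learner.

    Defaults follow the full-scale training protocol (gamma 0.99, policy
    learning rate 3e-5, critic 1e-4, batch 256, four 256-wide hidden layers,
    segment length 10); the desk-scale synthetic-walker runs override the
    network and batch sizes downward in their run configuration.
    """

    gamma: float = 0.99
    n_step: int = 5
    lr_policy: float = 3e-5
    lr_critic: float = 1e-4
    lr_alpha: float = 3e-4
    policy_hidden: tuple[int, ...] = (256, 256, 256, 256)
    critic_hidden: tuple[int, ...] = (256, 256, 256, 256)
    batch_segments: int = 26  # ~256 transitions at segment length 10
    twin_critics: bool = True
    polyak_tau: float = 0.005
    init_alpha: float = 0.1
    target_entropy: float | None = None  # None -> -act_dim
    value_rescale: bool = True
    entropy_in_bootstrap: bool = False

    def __post_init__(self):
        if not 0.0 < self.gamma <= 1.0:
            raise ContractError("gamma must be in (0, 1]")
        if not 1 <= self.n_step <= 10:
            raise ContractError("n_step must be in 1..10")


class SACAgent:
    """Multivariate-reward SAC learner bound to one environment layout."""

    def __init__(
        self,
        obs_dim: int,
        act_dim: int,
        weights: RewardWeights,
        config: SACConfig | None = None,
        seed: int = 0,
    ):
        self.obs_dim = obs_dim
        self.act_dim = act_dim
        self.weights = weights
        self.config = config or SACConfig()
        ss = np.random.SeedSequence(seed)
        pol_seed, c1_seed, c2_seed, self._sampler_seed = ss.spawn(4)
        self.rng = np.random.default_rng(self._sampler_seed)
        cfg = self.config
        self.policy = GaussianPolicy(
            obs_dim, act_dim, cfg.policy_hidden,
            rng=np.random.default_rng(pol_seed),
        )
        n_critics = 2 if cfg.twin_critics else 1
        crit_seeds = [c1_seed, c2_seed][:n_critics]
        self.critics = [
            MultiHeadCritic(
                obs_dim, act_dim, N_COMPONENTS, cfg.critic_hidden,
                rng=np.random.default_rng(s),
            )
            for s in crit_seeds
        ]
        self.target_critics = [c.copy() for c in self.critics]
        te = cfg.target_entropy if cfg.target_entropy is not None else -float(act_dim)
        self.temp = TemperatureState(
            log_alpha=np.array([np.log(cfg.init_alpha)]), target_entropy=te
        )
        self.opt_policy = Adam(self.policy.params, cfg.lr_policy)
        self.opt_critics = [Adam(c.params, cfg.lr_critic) for c in self.critics]
        self.opt_alpha = Adam({"log_alpha": self.temp.log_alpha}, cfg.lr_alpha)
        self.updates = 0

    def act(self, obs: np.ndarray, deterministic: bool = False):
        action, log_prob, _ = self.policy.sample(
            np.atleast_2d(obs), rng=self.rng, deterministic=deterministic
        )
        return action[0], float(log_prob[0])

    def update(self, replay, step: int | None = None) -> dict:
        """One prioritized gradient update; returns loss metrics."""
        cfg = self.config
        step = self.updates if step is None else step
        ids, segments, is_w = replay.sample(cfg.batch_segments, step, self.rng)
        batch = build_batch_from_segments(
            segments, is_w, cfg.gamma, cfg.n_step, cfg.value_rescale
        )
        targets = critic_targets(
            batch, self.policy, self.target_critics, self.temp, self.rng,
            cfg.value_rescale, cfg.entropy_in_bootstrap,
        )
        j_q_all = []
        resid = None
        for critic, opt in zip(self.critics, self.opt_critics):
            losses, grads, r = critic_loss_and_grads(batch, critic, targets)
            opt.step(grads)
            j_q_all.append(losses)
            resid = r if resid is None else np.minimum(np.abs(resid), np.abs(r))
        j_pi, pgrads, log_prob = actor_loss_and_grads(
            batch, self.policy, self.critics, self.temp, self.weights, rng=self.rng
        )
        self.opt_policy.step(pgrads)
        j_alpha, agrad = temperature_loss_and_grad(log_prob, self.temp)
        self.opt_alpha.step({"log_alpha": agrad})
        for critic, target in zip(self.critics, self.target_critics):
            polyak_update(target.params, critic.params, cfg.polyak_tau)

        # scalarized per-sample TD magnitudes -> segment priorities
        scalar_delta = np.abs(np.abs(resid) @ self.weights.w)
        deltas_per_segment: dict[int, list[float]] = {}
        for i, si in enumerate(batch.seg_index):
            deltas_per_segment.setdefault(int(si), []).append(float(scalar_delta[i]))
        seg_ids = []
        seg_deltas = []
        seen = set()
        for si, sid in enumerate(ids):
            if sid in seen:  # a segment sampled twice gets one update
                continue
            seen.add(sid)
            seg_ids.append(sid)
            seg_deltas.append(deltas_per_segment.get(si, [0.0]))
        replay.update_priorities(seg_ids, seg_deltas)
        self.updates += 1
        return {
            "J_pi": j_pi,
            "J_Q": np.mean([jq.sum() for jq in j_q_all]),
            "J_alpha": j_alpha,
            "alpha": self.temp.alpha,
        }

    # -- checkpointing -------------------------------------------------------

    def save(self, path) -> None:
        arrays: dict[str, np.ndarray] = {}
        for k, v in self.policy.params.items():
            arrays[f"policy/{k}"] = v
        for ci, c in enumerate(self.critics):
            for k, v in c.params.items():
                arrays[f"critic{ci}/{k}"] = v
        for ci, c in enumerate(self.target_critics):
            for k, v in c.params.items():
                arrays[f"target{ci}/{k}"] = v
        arrays["log_alpha"] = self.temp.log_alpha
        arrays["meta"] = np.array([self.obs_dim, self.act_dim, self.updates,
                                   len(self.critics)], dtype=np.int64)
        arrays["policy_sizes"] = np.array(self.policy.mlp.sizes, dtype=np.int64)
        arrays["critic_sizes"] = np.array(self.critics[0].mlp.sizes, dtype=np.int64)
        arrays["weights"] = self.weights.w
        arrays["component_names"] = np.array(list(REWARD_COMPONENTS))
        np.savez(path, **arrays)

    @classmethod
    def from_checkpoint(cls, path, config: SACConfig | None = None) -> "SACAgent":
        """Rebuild an agent with the architecture recorded in a checkpoint."""
        with np.load(path, allow_pickle=False) as z:
            obs_dim, act_dim, _, n_critics = (int(v) for v in z["meta"])
            policy_hidden = tuple(int(s) for s in z["policy_sizes"][1:-1])
            critic_hidden = tuple(int(s) for s in z["critic_sizes"][1:-1])
            weights = RewardWeights(w=z["weights"])
        cfg = config or SACConfig()
        cfg.policy_hidden = policy_hidden
        cfg.critic_hidden = critic_hidden
        cfg.twin_critics = n_critics == 2
        agent = cls(obs_dim, act_dim, weights, cfg, seed=0)
        agent.load_params(path)
        return agent

    def load_params(self, path) -> None:
        with np.load(path, allow_pickle=False) as z:
            for k in self.policy.params:
                self.policy.params[k][...] = z[f"policy/{k}"]
            for ci, c in enumerate(self.critics):
                for k in c.params:
                    c.params[k][...] = z[f"critic{ci}/{k}"]
            for ci, c in enumerate(self.target_critics):
                for k in c.params:
                    c.params[k][...] = z[f"target{ci}/{k}"]
            self.temp.log_alpha[...] = z["log_alpha"]
            self.updates = int(z["meta"][2])
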