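"""Multivariate SAC: squashed-Gaussian sampling, per-head Q scalarization,
value rescaling, n-step targets, losses, head surgery, and the agent loop."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gaitrl.errors import ContractError, ShapeError
from gaitrl.replay import Segment, Transition
from gaitrl.rewards import N_COMPONENTS, RewardWeights
from gaitrl.sac import (
    GaussianPolicy,
    MultiHeadCritic,
    SACAgent,
    SACConfig,
    TemperatureState,
    TrainBatch,
    actor_loss_and_grads,
    build_batch_from_segments,
    critic_loss_and_grads,
    critic_targets,
    head_surgery,
    n_step_target,
    q_scalar,
    sample_action,
    temperature_loss_and_grad,
    value_rescale,
    value_rescale_inverse,
)

OBS, ACT = 5, 3


@pytest.fixture
def policy():
    return GaussianPolicy(OBS, ACT, hidden=(16, 16), rng=np.random.default_rng(1))


@pytest.fixture
def critic():
    return MultiHeadCritic(OBS, ACT, N_COMPONENTS, hidden=(16, 16),
                           rng=np.random.default_rng(2))


def small_batch(rng, B=12):
    return TrainBatch(
        obs=rng.standard_normal((B, OBS)),
        act=rng.uniform(0, 1, (B, ACT)),
        rewards=rng.standard_normal((B, N_COMPONENTS)),
        next_obs=rng.standard_normal((B, OBS)),
        done=np.zeros(B, dtype=bool),
        discount=np.full(B, 0.99**3),
        weights=np.ones(B),
        seg_index=np.zeros(B, dtype=int),
    )


class TestSampling:
    def test_samples_stay_in_unit_box(self, policy, rng):
        obs = rng.standard_normal((10_000, OBS))
        action, _, _ = policy.sample(obs, rng=rng)
        assert np.all(action >= 0.0) and np.all(action <= 1.0)

    def test_same_seed_reproduces_action_and_log_prob(self, policy, rng):
        obs = rng.standard_normal(OBS)
        a1, lp1 = sample_action(policy, obs, seed=42)
        a2, lp2 = sample_action(policy, obs, seed=42)
        assert np.array_equal(a1, a2) and lp1 == lp2

    def test_zero_noise_returns_squashed_mean(self, policy, rng):
        obs = rng.standard_normal((4, OBS))
        mu, _, _ = policy.forward(obs)
        a_det, _, _ = policy.sample(obs, deterministic=True)
        assert np.allclose(a_det, 0.5 * (np.tanh(mu) + 1.0))
        a_eps, _, _ = policy.sample(obs, eps=np.zeros((4, ACT)))
        assert np.array_equal(a_det, a_eps)

    def test_wrong_observation_dimension_rejected(self, policy, rng):
        with pytest.raises(ShapeError):
            policy.sample(rng.standard_normal((2, OBS + 1)), rng=rng)

    def test_log_prob_matches_change_of_variables_identity(self, policy, rng):
        # analytic log pi against an independent density recomputation
        obs = rng.standard_normal((50, OBS))
        action, log_prob, aux = policy.sample(obs, rng=rng)
        u, mu, std = aux["u"], aux["mu"], aux["std"]
        log_gauss = (
            -0.5 * ((u - mu) / std) ** 2 - np.log(std) - 0.5 * np.log(2 * np.pi)
        ).sum(axis=1)
        jac = np.log(0.5 * (1 - np.tanh(u) ** 2) + 1e-12).sum(axis=1)
        assert np.allclose(log_prob, log_gauss - jac, atol=1e-9)


class TestQScalar:
    def test_constant_heads_sum_with_unit_weights(self):
        critic = MultiHeadCritic(OBS, ACT, 2, hidden=(8,), rng=np.random.default_rng(0))
        last = critic.mlp.n_layers - 1
        critic.mlp.params[f"W{last}"][...] = 0.0
        critic.mlp.params[f"b{last}"][...] = np.array([2.0, 3.0])
        out = q_scalar(critic, np.zeros((1, OBS)), np.zeros((1, ACT)), np.ones(2))
        assert out[0] == pytest.approx(5.0)

    def test_zero_weights_give_zero(self, critic, rng):
        out = q_scalar(
            critic, rng.standard_normal((4, OBS)), rng.uniform(0, 1, (4, ACT)),
            np.zeros(N_COMPONENTS),
        )
        assert np.allclose(out, 0.0)

    def test_matches_dot_product_oracle(self, critic, rng):
        for _ in range(50):
            obs = rng.standard_normal((3, OBS))
            act = rng.uniform(0, 1, (3, ACT))
            w = rng.uniform(0, 2, N_COMPONENTS)
            expected = critic.q_values(obs, act) @ w
            brute = np.array(
                [sum(qi * wi for qi, wi in zip(row, w))
                 for row in critic.q_values(obs, act)]
            )
            assert np.allclose(q_scalar(critic, obs, act, w), expected)
            assert np.allclose(expected, brute, atol=1e-12)

    def test_head_weight_mismatch_rejected(self, critic, rng):
        with pytest.raises(ShapeError):
            q_scalar(critic, np.zeros((1, OBS)), np.zeros((1, ACT)), np.ones(3))


class TestValueRescale:
    def test_zero_is_a_fixed_point(self):
        assert value_rescale(0.0) == 0.0
        assert value_rescale_inverse(0.0) == 0.0

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(x=st.floats(-1e6, 1e6))
    def test_odd_symmetry(self, x):
        assert value_rescale(-x) == pytest.approx(-value_rescale(x), abs=1e-12)

    def test_round_trip_within_1e9_on_ten_thousand_values(self, rng):
        x = rng.uniform(-1e4, 1e4, 10_000)
        assert np.max(np.abs(value_rescale_inverse(value_rescale(x)) - x)) < 1e-9

    def test_monotone_compression(self, rng):
        x = np.sort(rng.uniform(-100, 100, 1000))
        y = value_rescale(x)
        assert np.all(np.diff(y) > 0)
        assert np.all(np.abs(y[np.abs(x) > 10]) < np.abs(x[np.abs(x) > 10]))


class TestNStepTarget:
    def test_one_step_identity_without_rescale(self):
        r = np.ones((1, 2))
        boot = np.array([5.0, -1.0])
        t = n_step_target(r, boot, gamma=1.0, n=1, rescale=False)
        assert np.allclose(t, [6.0, 0.0])

    def test_terminated_zero_rewards_give_zero_target(self):
        t = n_step_target(
            np.zeros((2, 3)), np.full(3, 9.0), gamma=0.9, n=5, terminated=True
        )
        assert np.allclose(t, 0.0)  # h(0) = 0

    @pytest.mark.parametrize("n", [1, 2, 3, 4, 5])
    def test_matches_unrolled_sum_oracle(self, n, rng):
        H = 4
        rewards = rng.standard_normal((6, H))
        boot = rng.standard_normal(H)
        gamma = 0.95
        # independent unrolled-loop oracle
        expected = np.zeros(H)
        for h in range(H):
            acc = 0.0
            for k in range(n):
                acc += gamma**k * rewards[k, h]
            acc += gamma**n * boot[h]
            expected[h] = acc
        got = n_step_target(rewards, boot, gamma, n, rescale=False)
        assert np.allclose(got, expected, atol=1e-12)
        got_rs = n_step_target(rewards, value_rescale(boot), gamma, n, rescale=True)
        assert np.allclose(value_rescale_inverse(got_rs), expected, atol=1e-6)

    def test_horizon_too_short_without_termination_rejected(self, rng):
        with pytest.raises(ContractError):
            n_step_target(rng.standard_normal((2, 3)), np.zeros(3), 0.99, n=5)


class TestLosses:
    def test_critic_loss_zero_when_outputs_equal_targets(self, critic, rng):
        batch = small_batch(rng)
        targets = critic.q_values(batch.obs, batch.act)
        losses, grads, resid = critic_loss_and_grads(batch, critic, targets)
        assert np.allclose(losses, 0.0)
        assert all(np.allclose(g, 0.0) for g in grads.values())

    def test_temperature_loss_zero_at_target_entropy(self):
        temp = TemperatureState(target_entropy=-3.0)
        log_prob = np.full(10, 3.0)  # E[-log pi] = -3 = H_bar
        j_alpha, grad = temperature_loss_and_grad(log_prob, temp)
        assert j_alpha == pytest.approx(0.0)
        assert np.allclose(grad, 0.0)

    def test_actor_gradient_step_decreases_objective(self, policy, critic, rng):
        batch = small_batch(rng)
        temp = TemperatureState(target_entropy=-float(ACT))
        w = RewardWeights()
        eps = rng.standard_normal((len(batch), ACT))
        j0, grads, _ = actor_loss_and_grads(
            batch, policy, [critic], temp, w, eps=eps
        )
        lr = 1e-4
        for k, g in grads.items():
            policy.params[k] -= lr * g
        j1, _, _ = actor_loss_and_grads(batch, policy, [critic], temp, w, eps=eps)
        assert j1 < j0

    def test_actor_gradients_match_finite_differences(self, rng):
        policy = GaussianPolicy(OBS, ACT, hidden=(8,), rng=np.random.default_rng(5))
        critic = MultiHeadCritic(OBS, ACT, N_COMPONENTS, hidden=(8,),
                                 rng=np.random.default_rng(6))
        batch = small_batch(rng, B=4)
        temp = TemperatureState(target_entropy=-3.0)
        w = RewardWeights()
        eps = rng.standard_normal((4, ACT))
        _, grads, _ = actor_loss_and_grads(batch, policy, [critic], temp, w, eps=eps)

        def loss():
            j, _, _ = actor_loss_and_grads(
                batch, policy, [critic], temp, w, eps=eps
            )
            return j

        h = 1e-6
        for key in ("W0", "b1"):
            p = policy.params[key]
            flat_idx = [(0, 0) if p.ndim == 2 else (0,),
                        (p.shape[0] - 1, p.shape[-1] - 1) if p.ndim == 2 else (p.shape[0] - 1,)]
            for idx in flat_idx:
                old = p[idx]
                p[idx] = old + h
                fp = loss()
                p[idx] = old - h
                fm = loss()
                p[idx] = old
                num = (fp - fm) / (2 * h)
                assert grads[key][idx] == pytest.approx(num, abs=1e-5)

    def test_zero_weight_head_does_not_interfere_with_actor_objective(
        self, policy, critic, rng
    ):
        """Actor objective with a zero-weighted component equals the
        objective after surgically removing that head entirely."""
        batch = small_batch(rng)
        temp = TemperatureState(target_entropy=-3.0)
        idx = 7
        w = np.ones(N_COMPONENTS)
        w[idx] = 0.0
        weights = RewardWeights(w=w)
        eps = rng.standard_normal((len(batch), ACT))
        j_with, _, _ = actor_loss_and_grads(
            batch, policy, [critic], temp, weights, eps=eps
        )
        removed, _ = head_surgery(critic, "remove", idx)
        j_without, _, _ = actor_loss_and_grads(
            batch, policy, [removed], temp, weights, eps=eps
        )
        assert j_with == pytest.approx(j_without, abs=1e-12)

    def test_alpha_zero_single_head_reduces_to_negative_q_surrogate(
        self, policy, rng
    ):
        critic1 = MultiHeadCritic(OBS, ACT, 1, hidden=(16,),
                                  rng=np.random.default_rng(8))
        batch = small_batch(rng)
        temp = TemperatureState(log_alpha=np.array([-745.0]))  # alpha ~ 0
        w = RewardWeights()
        w.w = np.ones(1)  # single head
        eps = rng.standard_normal((len(batch), ACT))
        j_pi, _, _ = actor_loss_and_grads(batch, policy, [critic1], temp, w, eps=eps)
        action, _, _ = policy.sample(batch.obs, eps=eps)
        q = critic1.q_values(batch.obs, action)[:, 0]
        assert j_pi == pytest.approx(-np.mean(q), abs=1e-9)

    def test_losses_invariant_to_batch_ordering(self, policy, critic, rng):
        batch = small_batch(rng)
        temp = TemperatureState(target_entropy=-3.0)
        w = RewardWeights()
        eps = rng.standard_normal((len(batch), ACT))
        perm = rng.permutation(len(batch))
        shuffled = batch.permuted(perm)

        j1, _, lp1 = actor_loss_and_grads(batch, policy, [critic], temp, w, eps=eps)
        j2, _, lp2 = actor_loss_and_grads(
            shuffled, policy, [critic], temp, w, eps=eps[perm]
        )
        assert j1 == pytest.approx(j2, abs=1e-12)

        targets = critic.q_values(batch.next_obs, batch.act)  # fixed targets
        l1, _, _ = critic_loss_and_grads(batch, critic, targets)
        l2, _, _ = critic_loss_and_grads(shuffled, critic, targets[perm])
        assert np.allclose(l1, l2, atol=1e-12)

        a1, _ = temperature_loss_and_grad(lp1, temp)
        a2, _ = temperature_loss_and_grad(lp2, temp)
        assert a1 == pytest.approx(a2, abs=1e-12)

    def test_critic_targets_use_termination_to_cut_bootstrap(self, policy, critic, rng):
        batch = small_batch(rng)
        batch.done[:] = True
        batch.discount[:] = 0.0
        t = critic_targets(
            batch, policy, [critic], TemperatureState(), np.random.default_rng(0)
        )
        assert np.allclose(t, value_rescale(batch.rewards))


class TestHeadSurgery:
    def test_remove_equals_zero_weight_scalarization(self, critic, rng):
        obs = rng.standard_normal((20, OBS))
        act = rng.uniform(0, 1, (20, ACT))
        i = 3
        removed, _ = head_surgery(critic, "remove", i)
        w = np.ones(N_COMPONENTS)
        w_zeroed = w.copy()
        w_zeroed[i] = 0.0
        assert np.allclose(
            q_scalar(removed, obs, act, w), q_scalar(critic, obs, act, w_zeroed)
        )

    def test_add_then_remove_restores_scalar_q(self, critic, rng):
        obs = rng.standard_normal((10, OBS))
        act = rng.uniform(0, 1, (10, ACT))
        w0 = np.ones(N_COMPONENTS)
        base = q_scalar(critic, obs, act, w0)
        added, w1 = head_surgery(critic, "add", weights=w0, rng=rng)
        pruned, w2 = head_surgery(added, "remove", index=N_COMPONENTS, weights=w1)
        assert np.allclose(q_scalar(pruned, obs, act, w2), base)

    def test_add_leaves_existing_heads_bitwise_unchanged(self, critic, rng):
        obs = rng.standard_normal((100, OBS))
        act = rng.uniform(0, 1, (100, ACT))
        before = critic.q_values(obs, act)
        added, _ = head_surgery(critic, "add", rng=rng)
        after = added.q_values(obs, act)
        assert np.array_equal(after[:, :N_COMPONENTS], before)
        assert added.n_heads == N_COMPONENTS + 1

    def test_remove_out_of_range_rejected(self, critic):
        with pytest.raises(ContractError):
            head_surgery(critic, "remove", index=N_COMPONENTS)


class TestBatchBuilding:
    @staticmethod
    def _segment(rng, length=6, done_at=None):
        trs = []
        for t in range(length):
            trs.append(
                Transition(
                    observation=rng.standard_normal(OBS),
                    action=rng.uniform(0, 1, ACT),
                    reward=rng.standard_normal(N_COMPONENTS),
                    next_observation=rng.standard_normal(OBS),
                    done=(t == done_at),
                    episode_id=0,
                    t=t,
                )
            )
        return Segment(transitions=trs, mask=np.ones(length, dtype=bool))

    def test_n_step_sums_match_brute_force(self, rng):
        seg = self._segment(rng)
        gamma, n = 0.9, 3
        batch = build_batch_from_segments([seg], np.ones(1), gamma, n)
        for t in range(6):
            k_max = min(n, 6 - t)
            expected = sum(
                gamma**k * seg.transitions[t + k].reward for k in range(k_max)
            )
            assert np.allclose(batch.rewards[t], expected)
            assert batch.discount[t] == pytest.approx(gamma**k_max)

    def test_termination_truncates_window(self, rng):
        seg = self._segment(rng, done_at=2)
        batch = build_batch_from_segments([seg], np.ones(1), 0.9, 5)
        # element at t=0 stops accumulating at the terminal step t=2
        expected = (
            seg.transitions[0].reward
            + 0.9 * seg.transitions[1].reward
            + 0.81 * seg.transitions[2].reward
        )
        assert np.allclose(batch.rewards[0], expected)
        assert batch.discount[0] == 0.0 and batch.done[0]


class TestAgent:
    def test_update_produces_finite_metrics_and_priorities(self, rng):
        from gaitrl.replay import SegmentReplay

        agent = SACAgent(
            OBS, ACT, RewardWeights(),
            SACConfig(policy_hidden=(16,), critic_hidden=(16,),
                      batch_segments=4),
            seed=0,
        )
        replay = SegmentReplay(capacity_transitions=1000, segment_length=4)
        eid = replay.next_episode_id()
        episode = [
            Transition(
                observation=rng.standard_normal(OBS),
                action=rng.uniform(0, 1, ACT),
                reward=rng.standard_normal(N_COMPONENTS) * 0.1,
                next_observation=rng.standard_normal(OBS),
                done=(t == 19),
                episode_id=eid,
                t=t,
            )
            for t in range(20)
        ]
        replay.add_episode(episode)
        m1 = agent.update(replay)
        m2 = agent.update(replay)
        for m in (m1, m2):
            assert np.isfinite(m["J_pi"]) and np.isfinite(m["J_Q"])
            assert m["alpha"] > 0

    def test_from_checkpoint_rebuilds_recorded_architecture(self, tmp_path):
        agent = SACAgent(
            OBS, ACT, RewardWeights(),
            SACConfig(policy_hidden=(24, 12), critic_hidden=(20,),
                      batch_segments=2),
            seed=5,
        )
        path = tmp_path / "arch.npz"
        agent.save(path)
        loaded = SACAgent.from_checkpoint(path)
        assert loaded.policy.mlp.sizes == agent.policy.mlp.sizes
        assert loaded.critics[0].mlp.sizes == agent.critics[0].mlp.sizes
        assert len(loaded.critics) == len(agent.critics)
        for k in agent.policy.params:
            assert np.array_equal(loaded.policy.params[k], agent.policy.params[k])

    def test_checkpoint_round_trip_restores_parameters(self, tmp_path, rng):
        agent = SACAgent(
            OBS, ACT, RewardWeights(),
            SACConfig(policy_hidden=(8,), critic_hidden=(8,), batch_segments=2),
            seed=3,
        )
        path = tmp_path / "ckpt.npz"
        agent.save(path)
        agent2 = SACAgent(
            OBS, ACT, RewardWeights(),
            SACConfig(policy_hidden=(8,), critic_hidden=(8,), batch_segments=2),
            seed=99,
        )
        agent2.load_params(path)
        for k in agent.policy.params:
            assert np.array_equal(agent.policy.params[k], agent2.policy.params[k])
        for c1, c2 in zip(agent.critics, agent2.critics):
            for k in c1.params:
                assert np.array_equal(c1.params[k], c2.params[k])
        assert agent2.temp.alpha == agent.temp.alpha
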