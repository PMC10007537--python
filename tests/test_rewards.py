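"""Reward-term semantics: alive/step/velocity/effort terms, shaping terms,
IMU deviation penalties, entropy bonus, and weighted scalarization."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gaitrl.errors import ShapeError, ValidationError
from gaitrl.rewards import (
    ALIVE_BONUS,
    N_COMPONENTS,
    IMUTriplet,
    RewardVector,
    RewardWeights,
    assemble_and_scalarize,
    assemble_reward_vector,
    entropy_term,
    imu_terms,
    shaping_terms,
    target_achievement_bonus,
    tor_reward_terms,
    wrap_angle,
)


class TestTorTerms:
    def test_single_nonfallen_timestep_alive_bonus(self, kin_factory, unit_weights):
        r_alive, *_ = tor_reward_terms([kin_factory(fallen=False)], unit_weights)
        assert r_alive == pytest.approx(ALIVE_BONUS)

    def test_fallen_timestep_earns_no_alive_bonus(self, kin_factory, unit_weights):
        r_alive, *_ = tor_reward_terms([kin_factory(fallen=True)], unit_weights)
        assert r_alive == 0.0

    def test_zero_activations_give_zero_effort_cost(self, kin_factory, unit_weights):
        traj = [kin_factory(activations=np.zeros(6)) for _ in range(10)]
        _, _, _, c_eff, _ = tor_reward_terms(traj, unit_weights)
        assert c_eff == 0.0

    def test_matched_velocity_gives_zero_velocity_cost(self, kin_factory, unit_weights):
        traj = [kin_factory(v_body=(1.25, 0.0), v_tgt=(1.25, 0.0)) for _ in range(10)]
        _, _, c_vel, _, _ = tor_reward_terms(traj, unit_weights)
        assert c_vel == pytest.approx(0.0)

    def test_step_reward_integrates_in_step_time(self, kin_factory, unit_weights):
        # one step lasting 30 consecutive in-step samples at dt = 0.01
        traj = [kin_factory(in_step=True, dt=0.01) for _ in range(30)]
        _, r_step, *_ = tor_reward_terms(traj, unit_weights)
        assert r_step == pytest.approx(0.30)

    def test_out_of_step_samples_do_not_accrue(self, kin_factory, unit_weights):
        traj = [kin_factory(in_step=False) for _ in range(30)]
        _, r_step, c_vel, c_eff, _ = tor_reward_terms(traj, unit_weights)
        assert r_step == 0.0 and c_vel == 0.0 and c_eff == 0.0

    def test_env_reward_combines_terms_with_weights(self, kin_factory):
        w = RewardWeights(w_step=2.0, w_vel=0.5, w_eff=0.25)
        traj = [kin_factory() for _ in range(20)]
        r_alive, r_step, c_vel, c_eff, r_env = tor_reward_terms(traj, w)
        assert r_env == pytest.approx(
            r_alive + 2.0 * r_step - 0.5 * c_vel - 0.25 * c_eff
        )

    def test_empty_trajectory_rejected(self, unit_weights):
        with pytest.raises(ValidationError):
            tor_reward_terms([], unit_weights)

    def test_costs_are_nonnegative_on_random_trajectories(
        self, kin_factory, unit_weights, rng
    ):
        for _ in range(20):
            traj = [
                kin_factory(
                    v_body=rng.normal(size=2),
                    v_tgt=rng.normal(size=2),
                    activations=rng.uniform(0, 1, 6),
                    in_step=bool(rng.integers(2)),
                )
                for _ in range(15)
            ]
            _, _, c_vel, c_eff, _ = tor_reward_terms(traj, unit_weights)
            assert c_vel >= 0.0 and c_eff >= 0.0


class TestShapingTerms:
    def test_zero_action_gives_zero_effort_penalty(self, kin_factory):
        _, _, _, r_dep, _ = shaping_terms(kin_factory(), np.zeros(6))
        assert r_dep == 0.0

    def test_pelvis_velocity_bonus_is_speed(self, kin_factory):
        kin = kin_factory(v_body=(0.3, 0.4))
        _, r_pvb, *_ = shaping_terms(kin, np.zeros(6))
        assert r_pvb == pytest.approx(0.5)

    @pytest.mark.parametrize(
        "speed,expected",
        [(0.8, 0.0), (0.71, 0.0), (0.6, 0.1), (0.7, 0.1), (0.51, 0.1),
         (0.0, 1.0), (0.5, 1.0 - 3.5 * 0.25), (0.3, 1.0 - 3.5 * 0.09)],
    )
    def test_target_achievement_bonus_piecewise(self, speed, expected):
        assert target_achievement_bonus(speed) == pytest.approx(expected)

    def test_target_bonus_branch_values_are_nonincreasing(self):
        assert target_achievement_bonus(0.0) == 1.0
        assert target_achievement_bonus(0.6) == pytest.approx(0.1)
        assert target_achievement_bonus(0.9) == 0.0

    def test_crossed_feet_are_penalized_uncrossed_are_not(self, kin_factory):
        uncrossed = kin_factory(r_left=(0.2, 0.12, 0.0), r_right=(0.1, -0.12, 0.0))
        crossed = kin_factory(r_left=(0.2, -0.12, 0.0), r_right=(0.1, 0.12, 0.0))
        r_clp_u, *_ = shaping_terms(uncrossed, np.zeros(6))
        r_clp_c, *_ = shaping_terms(crossed, np.zeros(6))
        assert r_clp_u == 0.0
        assert r_clp_c < 0.0

    def test_velocity_deviation_penalty_only_in_step(self, kin_factory):
        kin_in = kin_factory(v_body=(0.0, 0.0), v_tgt=(1.0, 0.0), in_step=True)
        kin_out = kin_factory(v_body=(0.0, 0.0), v_tgt=(1.0, 0.0), in_step=False)
        assert shaping_terms(kin_in, np.zeros(6))[2] == pytest.approx(-1.0)
        assert shaping_terms(kin_out, np.zeros(6))[2] == 0.0

    def test_penalty_terms_have_correct_signs(self, kin_factory, rng):
        for _ in range(25):
            kin = kin_factory(
                v_body=rng.normal(size=2), v_tgt=rng.normal(size=2) * 0.5,
                in_step=bool(rng.integers(2)),
            )
            action = rng.uniform(0, 1, 6)
            r_clp, r_pvb, r_vdp, r_dep, r_tab = shaping_terms(kin, action)
            assert r_clp <= 0 and r_vdp <= 0 and r_dep <= 0
            assert r_pvb >= 0 and 0 <= r_tab <= 1

    def test_degenerate_torso_geometry_rejected(self, kin_factory):
        kin = kin_factory(r_head=(0.0, 0.0, 0.92))  # head == pelvis
        with pytest.raises(ValidationError):
            shaping_terms(kin, np.zeros(6))


class TestImuTerms:
    def test_identical_triplets_give_zero(self):
        t = IMUTriplet(0.1, -0.2, 0.3)
        assert imu_terms(t, t) == (0.0, 0.0, 0.0)

    def test_absolute_deviation_per_axis(self):
        col = IMUTriplet(0.2, 0.0, 0.0)
        obs = IMUTriplet(0.5, 0.0, 0.0)
        r_roll, r_pitch, r_yaw = imu_terms(col, obs)
        assert r_roll == pytest.approx(-0.3)
        assert r_pitch == 0.0 and r_yaw == 0.0

    def test_symmetric_in_arguments(self, rng):
        for _ in range(20):
            a = IMUTriplet(*rng.uniform(-3, 3, 3))
            b = IMUTriplet(*rng.uniform(-3, 3, 3))
            assert imu_terms(a, b) == pytest.approx(imu_terms(b, a), abs=1e-12)

    def test_wrapping_avoids_two_pi_cliff(self):
        near_pi = IMUTriplet(np.pi - 0.01, 0.0, 0.0)
        past_pi = IMUTriplet(-np.pi + 0.01, 0.0, 0.0)
        r_roll, _, _ = imu_terms(near_pi, past_pi)
        assert r_roll == pytest.approx(-0.02, abs=1e-9)

    def test_terms_never_positive(self, rng):
        for _ in range(50):
            a = IMUTriplet(*rng.uniform(-np.pi, np.pi, 3))
            b = IMUTriplet(*rng.uniform(-np.pi, np.pi, 3))
            assert all(r <= 0 for r in imu_terms(a, b))


class TestEntropyTerm:
    def test_zero_temperature_is_zero(self):
        assert entropy_term(0.0, -5.0) == 0.0
        assert entropy_term(0.0, 12.0) == 0.0

    def test_alpha_times_negative_log_prob(self):
        assert entropy_term(1.0, -2.0) == pytest.approx(2.0)
        assert entropy_term(0.5, -2.0) == pytest.approx(1.0)

    def test_negative_temperature_rejected(self):
        with pytest.raises(ValidationError):
            entropy_term(-0.1, 0.0)

    def test_gaussian_entropy_recovered_by_monte_carlo(self, rng):
        # E[-log N(x; 0, I_d)] = (d/2) ln(2 pi e) for a unit Gaussian
        d = 4
        n = 20000
        x = rng.standard_normal((n, d))
        log_p = (-0.5 * x**2 - 0.5 * np.log(2 * np.pi)).sum(axis=1)
        h_mc = np.mean([entropy_term(1.0, lp) for lp in log_p])
        h_exact = 0.5 * d * np.log(2 * np.pi * np.e)
        assert h_mc == pytest.approx(h_exact, rel=0.02)


class TestScalarization:
    def test_unit_weights_sum_components(self):
        comps = np.linspace(-1, 1, N_COMPONENTS)
        comps[0] = 3.7 - comps[1:].sum()
        rv = RewardVector(comps)
        assert assemble_and_scalarize(rv, RewardWeights()) == pytest.approx(3.7)

    def test_zero_weight_component_is_ignored(self, rng):
        w = np.ones(N_COMPONENTS)
        w[4] = 0.0
        base = rng.normal(size=N_COMPONENTS)
        changed = base.copy()
        changed[4] = 99.0
        s1 = assemble_and_scalarize(RewardVector(base), RewardWeights(w=w))
        s2 = assemble_and_scalarize(RewardVector(changed), RewardWeights(w=w))
        assert s1 == pytest.approx(s2)

    def test_matches_dot_product_oracle(self, rng):
        for _ in range(1000):
            comps = rng.normal(size=N_COMPONENTS)
            w = rng.uniform(0, 2, N_COMPONENTS)
            expected = sum(c * wi for c, wi in zip(comps, w))  # brute force
            got = assemble_and_scalarize(RewardVector(comps), RewardWeights(w=w))
            assert got == pytest.approx(expected, abs=1e-12)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        a=st.floats(-10, 10), b=st.floats(-10, 10),
        seed=st.integers(0, 2**31 - 1),
    )
    def test_scalarization_is_linear(self, a, b, seed):
        r = np.random.default_rng(seed)
        r1 = r.normal(size=N_COMPONENTS)
        r2 = r.normal(size=N_COMPONENTS)
        w = RewardWeights(w=r.uniform(0, 2, N_COMPONENTS))
        lhs = assemble_and_scalarize(RewardVector(a * r1 + b * r2), w)
        rhs = a * assemble_and_scalarize(RewardVector(r1), w) + b * assemble_and_scalarize(RewardVector(r2), w)
        assert lhs == pytest.approx(rhs, abs=1e-9)

    def test_length_mismatch_rejected(self):
        rv = RewardVector(np.zeros(N_COMPONENTS))
        bad = RewardWeights()
        bad.w = np.ones(3)  # bypass validation to exercise the check
        with pytest.raises(ShapeError):
            assemble_and_scalarize(rv, bad)


class TestAssembledVector:
    def test_zero_imu_weights_reproduce_baseline_scalar_exactly(
        self, kin_factory, rng
    ):
        """With the IMU weights zeroed, the scalar reward on any trajectory
        is bitwise-equal to a no-IMU configuration's scalar reward."""
        baseline = RewardWeights.baseline()
        for _ in range(20):
            kin = kin_factory(
                v_body=rng.normal(size=2), activations=rng.uniform(0, 1, 6)
            )
            action = rng.uniform(0, 1, 6)
            col = IMUTriplet(*rng.uniform(-1, 1, 3))
            obs = IMUTriplet(*rng.uniform(-1, 1, 3))
            rv = assemble_reward_vector(
                kin, action, baseline, 0.2, -1.3, col, obs
            )
            rv_no_imu = assemble_reward_vector(
                kin, action, baseline, 0.2, -1.3, col, col  # zero deviation
            )
            s = assemble_and_scalarize(rv, baseline)
            s_no = assemble_and_scalarize(rv_no_imu, baseline)
            assert s == s_no  # bitwise equality, not approx

    def test_vector_has_ten_finite_components_in_order(self, kin_factory):
        rv = assemble_reward_vector(
            kin_factory(), np.full(6, 0.3), RewardWeights(), 0.1, -2.0,
            IMUTriplet(0.1, 0, 0), IMUTriplet(0, 0, 0),
        )
        assert rv.components.shape == (10,)
        assert np.all(np.isfinite(rv.components))
        assert rv.names[0] == "r_env" and rv.names[-1] == "r_imu_yaw"


def test_wrap_angle_maps_into_half_open_interval(rng):
    x = rng.uniform(-20, 20, 500)
    w = wrap_angle(x)
    assert np.all(w > -np.pi) and np.all(w <= np.pi)
    # wrapping preserves the angle modulo 2 pi
    d = w - x
    assert np.allclose(np.cos(d), 1.0, atol=1e-9)
    assert np.allclose(np.sin(d), 0.0, atol=1e-7)
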