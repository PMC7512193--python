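"""Trajectory accounting and the fluctuation-theorem enumeration oracles."""

import math

import numpy as np
import pytest

from thermodecide import (
    ActionSpace,
    DecisionTrajectory,
    Policy,
    QuadraticUtility,
    UtilityEpoch,
    UtilityProtocol,
    accepted_path_logprob,
    anytime_rejection_policy,
    backward_trajectory_logprob,
    crooks_check,
    deliberation_cost,
    delta_free_energy,
    dissipated_utility,
    enumerate_trajectories,
    episodic_delta_free_energy,
    episodic_net_utility,
    equilibrium_policy,
    forward_trajectory_logprob,
    jarzynski_estimate,
    kl_divergence,
    lag_protocol_kernels,
    mh_protocol_kernels,
    net_utility_deliberation,
    sample_trajectories,
    second_law_check,
    trajectory_ledger,
    utility_gain_no_deliberation,
)
from thermodecide.thermo import kernel_power

from conftest import random_instance


class TestUtilityGain:
    def test_constant_protocol_gains_nothing(self):
        space = ActionSpace(range(3))
        proto = UtilityProtocol(space, [np.ones(3)] * 3)
        traj = DecisionTrajectory([0, 1, 2], "no-deliberation")
        assert utility_gain_no_deliberation(traj, proto) == 0.0

    def test_single_step_gain(self):
        space = ActionSpace(range(2))
        proto = UtilityProtocol(space, [np.array([0.0, 0.0]), np.array([1.0, 0.0])])
        assert utility_gain_no_deliberation(
            DecisionTrajectory([0, 1], "no-deliberation"), proto
        ) == 1.0
        # the final decision never contributes
        assert utility_gain_no_deliberation(
            DecisionTrajectory([1, 0], "no-deliberation"), proto
        ) == 0.0

    def test_regime_mismatch_rejected(self):
        space = ActionSpace(range(2))
        proto = UtilityProtocol(space, [np.zeros(2), np.ones(2)])
        with pytest.raises(ValueError, match="regime"):
            utility_gain_no_deliberation(DecisionTrajectory([0, 1], "deliberation"), proto)

    def test_work_heat_telescoping(self, rng):
        # per-trajectory work + heat sums to the total utility change
        _, prior, proto, beta = random_instance(rng)
        N = proto.n_transitions
        for _ in range(20):
            x = rng.integers(0, proto.space.size, size=N + 1)
            work = sum(proto.u(n)[x[n - 1]] - proto.u(n - 1)[x[n - 1]] for n in range(1, N + 1))
            heat = sum(proto.u(n)[x[n]] - proto.u(n)[x[n - 1]] for n in range(1, N + 1))
            total = proto.u(N)[x[N]] - proto.u(0)[x[0]]
            assert work + heat == pytest.approx(total, abs=1e-12)

    def test_mean_gain_below_free_energy_difference(self, rng):
        space = ActionSpace(range(6))
        prior = Policy.uniform(space)
        proto = UtilityProtocol(space, [rng.uniform(size=6), rng.uniform(size=6)])
        beta = 2.0
        kernels = lag_protocol_kernels(prior, proto, beta)
        _, u = sample_trajectories(proto, kernels, prior, beta, 10_000, rng, "no-deliberation")
        dF = delta_free_energy(prior, proto, beta)
        se = u.std(ddof=1) / 100.0
        assert u.mean() <= dF + 3 * se


class TestDeliberationCost:
    def test_identical_kernels_cost_nothing(self, rng):
        _, prior, proto, beta = random_instance(rng)
        K = mh_protocol_kernels(prior, proto, beta)[1]
        assert deliberation_cost(0, 1, K, K) == 0.0

    def test_matches_direct_matrix_lookup(self, rng):
        space, prior, proto, beta = random_instance(rng, n_actions=3, n_epochs=2)
        kernels = mh_protocol_kernels(prior, proto, beta)
        for xp in range(3):
            for xn in range(3):
                expected = kernels[1].logtrans[xp, xn] - kernels[0].logtrans[xp, xn]
                assert deliberation_cost(xn, xp, kernels[1], kernels[0]) == pytest.approx(
                    expected, abs=1e-14
                )

    def test_expected_cost_is_conditional_kl(self, rng):
        space, prior, proto, beta = random_instance(rng, n_actions=4, n_epochs=2)
        kernels = mh_protocol_kernels(prior, proto, beta, sweeps=2)
        for xp in range(4):
            row_now = np.exp(kernels[1].logtrans[xp])
            kl = float(
                np.sum(row_now * (kernels[1].logtrans[xp] - kernels[0].logtrans[xp]))
            )
            mean_cost = sum(
                row_now[xn] * deliberation_cost(xn, xp, kernels[1], kernels[0])
                for xn in range(4)
            )
            assert mean_cost == pytest.approx(kl, abs=1e-12)
            assert kl >= -1e-12


class TestTrajectoryMeasures:
    def test_forward_measure_normalizes(self, rng):
        _, prior, proto, beta = random_instance(rng, n_actions=3, n_epochs=3)
        kernels = mh_protocol_kernels(prior, proto, beta)
        _, fwd, _ = enumerate_trajectories(proto, kernels, prior, beta)
        assert np.exp(fwd).sum() == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("regime", ["deliberation", "no-deliberation"])
    def test_backward_measure_normalizes(self, rng, regime):
        _, prior, proto, beta = random_instance(rng, n_actions=3, n_epochs=3)
        kernels = (
            mh_protocol_kernels(prior, proto, beta)
            if regime == "deliberation"
            else lag_protocol_kernels(prior, proto, beta)
        )
        trajs, _, _ = enumerate_trajectories(proto, kernels, prior, beta, regime)
        total = sum(
            math.exp(
                backward_trajectory_logprob(
                    DecisionTrajectory(t, regime), proto, kernels, prior, beta
                )
            )
            for t in trajs
        )
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_single_epoch_equilibrium_start(self, rng):
        space, prior, proto, beta = random_instance(rng, n_actions=3, n_epochs=2)
        kernels = mh_protocol_kernels(prior, proto, beta)
        eq0 = equilibrium_policy(prior, UtilityEpoch(proto.u(0)), beta)
        traj = DecisionTrajectory([1, 2], "deliberation")
        lp = forward_trajectory_logprob(traj, kernels, eq0)
        assert lp == pytest.approx(eq0.logp[1] + kernels[1].logtrans[1, 2], abs=1e-14)

    def test_time_symmetric_protocol_has_symmetric_measures(self, rng):
        # constant utilities with fully equilibrated kernels (the zero
        # dissipation case): every trajectory is as probable backwards
        space = ActionSpace(range(3))
        prior = Policy.from_probs(space, rng.dirichlet(np.ones(3)))
        u = rng.uniform(size=3)
        proto = UtilityProtocol(space, [u, u, u])
        kernels = lag_protocol_kernels(prior, proto, 1.5)
        trajs, fwd, _ = enumerate_trajectories(proto, kernels, prior, 1.5)
        for t, f in zip(trajs, fwd):
            b = backward_trajectory_logprob(
                DecisionTrajectory(t, "deliberation"), proto, kernels, prior, 1.5
            )
            if f > -np.inf:
                assert f == pytest.approx(b, abs=1e-12)


class TestCrooksTheorem:
    @pytest.mark.parametrize("sweeps", [1, 3])
    def test_deliberation_oracle(self, rng, sweeps):
        for _ in range(10):
            _, prior, proto, beta = random_instance(rng)
            kernels = mh_protocol_kernels(prior, proto, beta, sweeps=sweeps)
            trajs, fwd, _ = enumerate_trajectories(proto, kernels, prior, beta)
            for t in trajs:
                lhs, rhs = crooks_check(
                    DecisionTrajectory(t, "deliberation"), proto, kernels, prior, beta
                )
                assert abs(lhs - rhs) < 1e-10

    def test_no_deliberation_oracle(self, rng):
        for _ in range(5):
            _, prior, proto, beta = random_instance(rng)
            kernels = lag_protocol_kernels(prior, proto, beta)
            trajs, _, _ = enumerate_trajectories(proto, kernels, prior, beta, "no-deliberation")
            for t in trajs:
                lhs, rhs = crooks_check(
                    DecisionTrajectory(t, "no-deliberation"), proto, kernels, prior, beta
                )
                assert abs(lhs - rhs) < 1e-10

    def test_quasistatic_trajectory_does_not_dissipate(self, rng):
        # constant protocol + equilibrated kernels: ratio 1 and U_diss = 0
        space = ActionSpace(range(4))
        prior = Policy.uniform(space)
        u = rng.uniform(size=4)
        proto = UtilityProtocol(space, [u, u])
        kernels = lag_protocol_kernels(prior, proto, 2.0)
        lhs, rhs = crooks_check(
            DecisionTrajectory([0, 3], "deliberation"), proto, kernels, prior, 2.0
        )
        assert lhs == pytest.approx(0.0, abs=1e-12)
        assert rhs == pytest.approx(0.0, abs=1e-12)

    def test_episodic_fixed_prior_relation(self, rng):
        # p(x)/p_eq(x) = exp(beta U_diss(x)) on an 8-action two-episode task
        space = ActionSpace(range(8))
        prior = Policy.uniform(space)
        dus = [UtilityEpoch(rng.uniform(size=8), i) for i in range(2)]
        beta, k = 1.5, 3
        policies = [
            anytime_rejection_policy(prior, du, beta, float(np.max(du.values)), k)
            for du in dus
        ]
        dF = episodic_delta_free_energy(prior, dus, beta)
        for x0 in range(8):
            for x1 in range(8):
                traj = DecisionTrajectory([x0, x1], "episodic-fixed-prior")
                unet = episodic_net_utility(traj, dus, policies, prior, beta)
                log_p = policies[0].logp[x0] + policies[1].logp[x1]
                eqs = [equilibrium_policy(prior, du, beta) for du in dus]
                log_peq = eqs[0].logp[x0] + eqs[1].logp[x1]
                assert log_p - log_peq == pytest.approx(
                    beta * dissipated_utility(unet, dF), abs=1e-10
                )


class TestJarzynskiEquality:
    def test_enumeration_oracle_deliberation(self, rng):
        for _ in range(10):
            _, prior, proto, beta = random_instance(rng)
            kernels = mh_protocol_kernels(prior, proto, beta)
            _, fwd, unet = enumerate_trajectories(proto, kernels, prior, beta)
            lhs = float(np.exp(fwd) @ np.exp(beta * unet))
            rhs = math.exp(beta * delta_free_energy(prior, proto, beta))
            assert lhs == pytest.approx(rhs, rel=1e-12)

    def test_enumeration_oracle_episodic(self, rng):
        space = ActionSpace(range(8))
        prior = Policy.uniform(space)
        dus = [UtilityEpoch(rng.uniform(size=8), i) for i in range(2)]
        beta, k = 1.0, 2
        policies = [
            anytime_rejection_policy(prior, du, beta, float(np.max(du.values)), k)
            for du in dus
        ]
        dF = episodic_delta_free_energy(prior, dus, beta)
        lhs = 0.0
        for x0 in range(8):
            for x1 in range(8):
                traj = DecisionTrajectory([x0, x1], "episodic-fixed-prior")
                unet = episodic_net_utility(traj, dus, policies, prior, beta)
                lhs += math.exp(
                    policies[0].logp[x0] + policies[1].logp[x1] + beta * unet
                )
        assert lhs == pytest.approx(math.exp(beta * dF), rel=1e-12)

    def test_monte_carlo_estimate_within_3se(self, rng):
        _, prior, proto, beta = random_instance(rng, n_actions=4, n_epochs=3, beta=1.0)
        kernels = mh_protocol_kernels(prior, proto, beta)
        _, unet = sample_trajectories(proto, kernels, prior, beta, 10_000, rng)
        est = jarzynski_estimate(unet, beta)
        target = math.exp(beta * delta_free_energy(prior, proto, beta))
        assert abs(est.mean - target) < 3 * est.se

    def test_zero_change_protocol_gives_unity(self, rng):
        space = ActionSpace(range(3))
        prior = Policy.uniform(space)
        u = rng.uniform(size=3)
        proto = UtilityProtocol(space, [u, u])
        kernels = lag_protocol_kernels(prior, proto, 1.0)
        _, unet = sample_trajectories(proto, kernels, prior, 1.0, 100, rng)
        est = jarzynski_estimate(unet, 1.0)
        assert est.mean == pytest.approx(1.0, abs=1e-14)

    def test_jensen_chain(self, rng):
        _, prior, proto, beta = random_instance(rng)
        kernels = mh_protocol_kernels(prior, proto, beta)
        _, unet = sample_trajectories(proto, kernels, prior, beta, 500, rng)
        est = jarzynski_estimate(unet, beta)
        assert est.free_energy_estimate >= unet.mean() - 1e-12

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            jarzynski_estimate(np.array([]), 1.0)


class TestSecondLaw:
    def test_enumeration_equality(self, rng):
        _, prior, proto, beta = random_instance(rng, n_actions=4, n_epochs=3)
        kernels = mh_protocol_kernels(prior, proto, beta)
        trajs, fwd, unet = enumerate_trajectories(proto, kernels, prior, beta)
        dF = delta_free_energy(prior, proto, beta)
        eq0 = equilibrium_policy(prior, UtilityEpoch(proto.u(0)), beta)
        bwd = np.array(
            [
                backward_trajectory_logprob(
                    DecisionTrajectory(t, "deliberation"), proto, kernels, prior, beta
                )
                for t in trajs
            ]
        )
        mean_diss, kl_est = second_law_check(dF - unet, fwd, bwd, beta, weights=np.exp(fwd))
        assert mean_diss == pytest.approx(kl_est, abs=1e-10)
        assert mean_diss >= 0.0

    def test_sampled_dissipation_non_negative(self, rng):
        _, prior, proto, beta = random_instance(rng, beta=1.0)
        kernels = mh_protocol_kernels(prior, proto, beta)
        _, unet = sample_trajectories(proto, kernels, prior, beta, 10_000, rng)
        dF = delta_free_energy(prior, proto, beta)
        diss = dF - unet
        se = diss.std(ddof=1) / 100.0
        assert diss.mean() >= -3 * se


class TestEpisodicAccounting:
    def test_infinite_budget_attains_free_energy(self, rng):
        space = ActionSpace(range(8))
        prior = Policy.uniform(space)
        dus = [UtilityEpoch(rng.uniform(size=8), i) for i in range(2)]
        beta = 1.0
        eqs = [equilibrium_policy(prior, du, beta) for du in dus]
        mean_unet = 0.0
        for du, pol in zip(dus, eqs):
            mean_unet += float(pol.probs @ (du.values - (pol.logp - prior.logp) / beta))
        assert mean_unet == pytest.approx(
            episodic_delta_free_energy(prior, dus, beta), abs=1e-12
        )

    def test_zero_budget_pays_no_cost(self, rng):
        space = ActionSpace(range(8))
        prior = Policy.uniform(space)
        dus = [UtilityEpoch(rng.uniform(size=8), i) for i in range(2)]
        beta = 1.0
        mean = sum(float(prior.probs @ du.values) for du in dus)
        # with the prior as policy the cost term vanishes identically
        traj = DecisionTrajectory([2, 5], "episodic-fixed-prior")
        unet = episodic_net_utility(traj, dus, [prior, prior], prior, beta)
        assert unet == pytest.approx(sum(du.values[x] for du, x in zip(dus, [2, 5])), abs=1e-12)
        assert mean <= episodic_delta_free_energy(prior, dus, beta) + 1e-12


class TestDissipatedUtility:
    def test_equilibrium_policy_dissipates_nothing(self, two_action):
        _, prior, du = two_action
        beta = 1.0
        eq = equilibrium_policy(prior, du, beta)
        unet = float(eq.probs @ (du.values - (eq.logp - prior.logp) / beta))
        from thermodecide import equilibrium_free_energy

        assert dissipated_utility(unet, equilibrium_free_energy(prior, du, beta)) == (
            pytest.approx(0.0, abs=1e-12)
        )

    def test_prior_policy_dissipation_is_kl(self, two_action):
        _, prior, du = two_action
        beta = 1.0
        from thermodecide import equilibrium_free_energy

        eq = equilibrium_policy(prior, du, beta)
        unet = float(prior.probs @ du.values)  # zero cost
        diss = dissipated_utility(unet, equilibrium_free_energy(prior, du, beta))
        assert diss == pytest.approx(kl_divergence(prior, eq) / beta, abs=1e-12)


class TestAcceptedPathLogprob:
    def test_single_uphill_move(self):
        u = QuadraticUtility(1.0, -2.0)  # mode 1
        init = lambda x: -0.5 * math.log(2 * math.pi) - 0.5 * x**2
        lp = accepted_path_logprob(np.array([0.0, 0.5]), [u], 1.0, 0.5, init)
        expected = init(0.0) + (
            -0.5 * math.log(2 * math.pi * 0.25) - 0.5 * 0.25 / 0.25
        )  # alpha = 1 uphill
        assert lp == pytest.approx(expected, abs=1e-12)

    def test_three_move_path_term_by_term(self):
        beta, sp = 1.0, 0.3
        u1 = QuadraticUtility(1.0, 0.0)
        u2 = QuadraticUtility(1.0, -2.0)
        path = np.array([0.2, -0.1, 0.4, 0.9])
        init = lambda x: 0.0
        lp = accepted_path_logprob(path, [u1, u2, u2], beta, sp, init)
        expect = 0.0
        for t, u in enumerate([u1, u2, u2], start=1):
            step = path[t] - path[t - 1]
            expect += -0.5 * math.log(2 * math.pi * sp**2) - 0.5 * step**2 / sp**2
            expect += min(0.0, beta * float(u.u(path[t]) - u.u(path[t - 1])))
        assert lp == pytest.approx(expect, abs=1e-12)

    def test_constant_utility_path_is_reversible(self):
        # forward and reversed scores coincide when starting log-densities
        # are the equilibrium of the single utility in force
        beta, sp = 2.0, 0.4
        u = QuadraticUtility(1.0, 0.0)
        var = 1.0 / (2 * beta * u.a)
        eq = lambda x: -0.5 * math.log(2 * math.pi * var) - 0.5 * x**2 / var
        path = np.array([0.1, -0.3, 0.25])
        f = accepted_path_logprob(path, [u, u], beta, sp, eq)
        b = accepted_path_logprob(path[::-1], [u, u], beta, sp, eq)
        assert f == pytest.approx(b, abs=1e-12)


class TestLedger:
    def test_ledger_consistency(self, rng):
        _, prior, proto, beta = random_instance(rng)
        kernels = mh_protocol_kernels(prior, proto, beta)
        x = rng.integers(0, proto.space.size, size=proto.n_transitions + 1)
        traj = DecisionTrajectory(x, "deliberation")
        led = trajectory_ledger(traj, proto, kernels, prior, beta)
        assert led.u_net == pytest.approx(
            net_utility_deliberation(traj, proto, kernels, beta), abs=1e-12
        )
        assert led.u_diss == pytest.approx(
            delta_free_energy(prior, proto, beta) - led.u_net, abs=1e-12
        )
        assert led.fwd_logp - led.bwd_logp == pytest.approx(beta * led.u_diss, abs=1e-10)
        assert led.warnings == ()

    def test_non_reversible_kernel_is_flagged(self, rng):
        from thermodecide.samplers import MarkovKernel

        space = ActionSpace(range(3))
        prior = Policy.uniform(space)
        proto = UtilityProtocol(space, [rng.uniform(size=3), rng.uniform(size=3)])
        cycle = np.array([[0.0, 1.0, 0.0], [0.0, 0.0, 1.0], [1.0, 0.0, 0.0]])
        with np.errstate(divide="ignore"):
            bad = MarkovKernel(space, np.log(cycle))
        kernels = [mh_protocol_kernels(prior, proto, 1.0)[0], bad]
        led = trajectory_ledger(
            DecisionTrajectory([0, 1], "deliberation"), proto, kernels, prior, 1.0
        )
        assert led.warnings

    def test_enumeration_cap(self, rng):
        space = ActionSpace(range(10))
        prior = Policy.uniform(space)
        proto = UtilityProtocol(space, [rng.uniform(size=10) for _ in range(8)])
        kernels = mh_protocol_kernels(prior, proto, 1.0)
        with pytest.raises(ValueError, match="cap"):
            enumerate_trajectories(proto, kernels, prior, 1.0)

    def test_kernel_power_composes(self, rng):
        _, prior, proto, beta = random_instance(rng, n_actions=4)
        K = mh_protocol_kernels(prior, proto, beta)[1]
        K3 = kernel_power(K, 3)
        np.testing.assert_allclose(K3.trans, np.linalg.matrix_power(K.trans, 3), atol=1e-12)
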