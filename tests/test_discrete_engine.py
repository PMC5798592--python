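import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from actinf._util import LOG_FLOOR, log_stable, softmax
from actinf.discrete_model import DiscreteModel, normalize_columns
from actinf.discrete_engine import (Message, _log_priors, _obs_logpots,
                                    ascending_message, backward_message,
                                    bayesian_model_average,
                                    descending_message, expected_free_energy,
                                    expected_outcomes, forward_message,
                                    likelihood_message, marginal_free_energy,
                                    policy_posterior, run_deep, run_trial,
                                    sample_outcome, select_action,
                                    state_update_fixed_point,
                                    state_update_gradient, step_process)
from actinf.exact_oracle import enumerate_posterior
from conftest import random_observations, random_small_model


def cycle_B(n):
    B = np.zeros((n, n))
    for s in range(n):
        B[(s + 1) % n, s] = 1.0
    return B


class TestMessages:
    def test_likelihood_identity_A_is_log_onehot(self):
        msg = likelihood_message(np.eye(3), 2)
        assert msg.argmax() == 2
        np.testing.assert_allclose(msg, log_stable(np.eye(3)[2]), atol=1e-12)

    def test_likelihood_uniform_A_is_constant(self):
        msg = likelihood_message(np.full((2, 3), 0.5), 0)
        assert np.ptp(msg) < 1e-12

    def test_likelihood_example_hand_computed(self):
        A = np.array([[0.9, 0.1], [0.1, 0.9]])
        np.testing.assert_allclose(likelihood_message(A, 0),
                                   np.log([0.9, 0.1]), atol=1e-12)

    def test_likelihood_out_of_range_outcome(self):
        with pytest.raises(IndexError):
            likelihood_message(np.eye(2), 5)

    def test_forward_identity_B_returns_log_state(self):
        s = np.array([0.3, 0.7])
        np.testing.assert_allclose(forward_message(np.eye(2), s),
                                   log_stable(s), atol=1e-12)

    def test_forward_permutation_advances_the_cycle(self):
        msg = forward_message(cycle_B(3), np.eye(3)[0])
        assert msg.argmax() == 1

    def test_forward_uniform_B_is_constant(self):
        msg = forward_message(np.full((3, 3), 1 / 3), np.array([0.2, 0.5, 0.3]))
        assert np.ptp(msg) < 1e-12

    def test_backward_permutation_retrodicts(self):
        msg = backward_message(cycle_B(3), np.eye(3)[1])
        assert msg.argmax() == 0

    def test_backward_uniform_inputs_are_constant(self):
        assert np.ptp(backward_message(cycle_B(3), np.full(3, 1 / 3))) < 1e-12
        assert np.ptp(backward_message(np.full((3, 3), 1 / 3),
                                       np.eye(3)[1])) < 1e-12

    def test_message_payloads_must_be_finite(self):
        with pytest.raises(ValueError):
            Message(target=(0, 0, 0), kind="forward",
                    payload=np.array([np.inf]))
        with pytest.raises(ValueError):
            Message(target=(0, 0, 0), kind="sideways", payload=np.zeros(2))


class TestStateUpdates:
    def test_deterministic_model_recovers_sequence(self):
        n = 3
        m = DiscreteModel(A=[np.eye(n)], B=[cycle_B(n)[:, :, None]],
                          D=[np.eye(n)[0]], T=3)
        s = state_update_fixed_point(m, [(0,), (1,), (2,)], tol=1e-10)
        for tau, true in enumerate((0, 1, 2)):
            assert s[0][tau].argmax() == true
            assert s[0][tau].max() > 1 - 1e-8

    def test_uniform_B_single_observation_matches_oracle(self, rng):
        n, T = 3, 3
        A = normalize_columns(rng.random((3, n)) + 0.1)
        m = DiscreteModel(A=[A], B=[np.full((n, n, 1), 1 / n)],
                          D=[normalize_columns(rng.random(n) + 0.1)], T=T)
        obs = [None, (1,), None]
        s = state_update_fixed_point(m, obs, tol=1e-12)
        exact = enumerate_posterior(m, obs)
        np.testing.assert_allclose(s[0], exact.marginals[0], atol=1e-8)

    def test_no_observations_approximates_prior_propagation(self, rng):
        # without outcomes the exact posterior is the forward propagation
        # of D through B; the message scheme reproduces it closely (its
        # non-cavity backward messages re-circulate a little prior
        # information, a known mild overconfidence of the scheme)
        m = random_small_model(rng, T=3, n_policies=1)
        s = state_update_fixed_point(m, None, tol=1e-12)
        expect = m.D[0]
        np.testing.assert_allclose(s[0][0], expect, atol=0.02)
        for tau in (1, 2):
            a = int(m.policies[min(tau - 1, m.policies.shape[0] - 1), 0, 0])
            expect = m.B[0][:, :, a] @ expect
            np.testing.assert_allclose(s[0][tau], expect, atol=0.02)

    def test_gradient_stationary_at_fixed_point(self, rng):
        m = random_small_model(rng, n_policies=1)
        obs = random_observations(rng, m)
        s_fp = state_update_fixed_point(m, obs, tol=1e-13)
        nu0 = [log_stable(s_fp[0])]
        s, nu, eps, F = state_update_gradient(m, obs, 0, iterations=1,
                                              nu0=nu0)
        # at the stationary point the error has equal components
        # (softmax gauge) and the expectations do not move
        for tau in range(m.T):
            assert np.ptp(eps[0][tau]) < 1e-8
        np.testing.assert_allclose(s[0], s_fp[0], atol=1e-7)

    def test_gradient_agrees_with_fixed_point_in_exact_regime(self, rng):
        n, T = 3, 3
        A = normalize_columns(rng.random((3, n)) + 0.1)
        m = DiscreteModel(A=[A], B=[np.full((n, n, 1), 1 / n)],
                          D=[np.full(n, 1 / n)], T=T)
        obs = [None, (2,), None]
        s_fp = state_update_fixed_point(m, obs, tol=1e-12)
        s_gd, *_ = state_update_gradient(m, obs, 0, iterations=400)
        np.testing.assert_allclose(s_gd[0], s_fp[0], atol=1e-6)

    def test_free_energy_endpoint_descent_on_random_models(self):
        """The gradient flow ends at lower marginal free energy than it
        starts on 100 random small models."""
        for k in range(100):
            r = np.random.default_rng(6000 + k)
            m = random_small_model(r)
            obs = random_observations(np.random.default_rng(6500 + k), m)
            for p in range(m.n_policies):
                *_, F = state_update_gradient(m, obs, p, iterations=16)
                assert F[-1] <= F[0] + 1e-9

    def test_fixed_point_convergence_error_carries_iterate(self, rng):
        m = random_small_model(rng, n_policies=1)
        from actinf.discrete_engine import ConvergenceError
        with pytest.raises(ConvergenceError) as err:
            state_update_fixed_point(m, None, tol=0.0, max_sweeps=2)
        assert err.value.last_iterate is not None


class TestExpectedOutcomes:
    def test_deterministic_A_onehot_state(self):
        o = expected_outcomes(np.eye(3), np.eye(3)[1])
        np.testing.assert_allclose(o, np.eye(3)[1], atol=1e-12)

    def test_uniform_state_gives_column_average(self, rng):
        A = normalize_columns(rng.random((4, 3)) + 0.1)
        o = expected_outcomes(A, np.full(3, 1 / 3))
        np.testing.assert_allclose(o, A.mean(axis=1), atol=1e-12)

    def test_identity_A_returns_the_state(self):
        s = np.array([0.2, 0.5, 0.3])
        np.testing.assert_allclose(expected_outcomes(np.eye(3), s), s)


class TestExpectedFreeEnergy:
    def test_zero_for_preference_matched_zero_ambiguity(self):
        # deterministic likelihood (H = 0), preferences equal to the
        # predicted outcome distribution -> exactly zero
        o = np.array([0.25, 0.75])
        s = o.copy()
        m = DiscreteModel(A=[np.eye(2)], B=[np.eye(2)[:, :, None]],
                          D=[np.full(2, 0.5)], T=1,
                          C=[log_stable(o)])
        G = expected_free_energy(m, [s[None, :]])
        assert G == 0.0

    def test_kl_example_by_hand(self):
        m = DiscreteModel(A=[np.eye(2)], B=[np.eye(2)[:, :, None]],
                          D=[np.full(2, 0.5)], T=1,
                          C=[np.log([0.5, 0.5])])
        G = expected_free_energy(m, [np.array([[1.0, 0.0]])])
        assert G == pytest.approx(np.log(2), abs=1e-6)

    def test_uniform_everything_is_zero(self):
        n = 4
        m = DiscreteModel(A=[np.eye(n)], B=[np.eye(n)[:, :, None]],
                          D=[np.full(n, 1 / n)], T=1,
                          C=[log_stable(np.full(n, 1 / n))])
        G = expected_free_energy(m, [np.full((1, n), 1 / n)])
        assert G == pytest.approx(0.0, abs=1e-12)


class TestPolicySelection:
    def test_equal_G_gives_uniform(self):
        np.testing.assert_allclose(policy_posterior(np.array([1.3, 1.3])),
                                   [0.5, 0.5])

    def test_softmax_example_by_hand(self):
        pi = policy_posterior(np.array([np.log(2), 0.0]), gamma=1.0)
        np.testing.assert_allclose(pi, [1 / 3, 2 / 3], atol=1e-12)

    def test_zero_gamma_is_uniform(self, rng):
        G = rng.normal(size=5)
        np.testing.assert_allclose(policy_posterior(G, gamma=0.0),
                                   np.full(5, 0.2))

    @given(arrays(float, 4, elements=st.floats(-5, 5)),
           st.floats(-3, 3))
    def test_gauge_invariance_under_constant_shift(self, G, c):
        np.testing.assert_allclose(policy_posterior(G),
                                   policy_posterior(G + c), atol=1e-9)

    def test_marginal_F_term_suppresses_implausible_policies(self):
        G = np.zeros(2)
        pi = policy_posterior(G, F=np.array([0.0, 50.0]))
        assert pi[0] > 0.999


class TestBMAAndAction:
    def test_identical_policies_average_to_themselves(self, rng):
        s = softmax(rng.normal(size=(3, 4)), axis=1)
        bma = bayesian_model_average([[s], [s]], np.array([0.4, 0.6]))
        np.testing.assert_allclose(bma[0], s, atol=1e-12)

    def test_onehot_policy_posterior_selects_policy(self, rng):
        s1 = softmax(rng.normal(size=(2, 3)), axis=1)
        s2 = softmax(rng.normal(size=(2, 3)), axis=1)
        bma = bayesian_model_average([[s1], [s2]], np.array([0.0, 1.0]))
        np.testing.assert_allclose(bma[0], s2, atol=1e-12)

    def test_convex_combination(self):
        s1 = np.array([[1.0, 0.0]])
        s2 = np.array([[0.0, 1.0]])
        bma = bayesian_model_average([[s1], [s2]], np.array([1 / 3, 2 / 3]))
        np.testing.assert_allclose(bma[0], [[1 / 3, 2 / 3]], atol=1e-12)

    def test_agreeing_policies_select_their_action(self):
        policies = np.array([[[2]], [[2]]]).transpose(1, 0, 2)
        assert select_action(np.array([0.1, 0.9]), policies, 0) == (2,)

    def test_most_probable_policy_wins(self):
        policies = np.array([[[1]], [[0]]]).transpose(1, 0, 2)
        assert select_action(np.array([0.7, 0.3]), policies, 0) == (1,)

    def test_tie_breaks_to_lowest_action_index(self):
        policies = np.array([[[2]], [[0]]]).transpose(1, 0, 2)
        assert select_action(np.array([0.5, 0.5]), policies, 0) == (0,)


class TestProcess:
    def make_deterministic(self):
        n = 3
        return DiscreteModel(A=[np.eye(n)], B=[cycle_B(n)[:, :, None]],
                             D=[np.eye(n)[0]], T=3)

    def test_deterministic_process_is_deterministic(self):
        m = self.make_deterministic()
        rng = np.random.default_rng(0)
        states, outcome = step_process(rng, m, (0,), ())
        assert states == (1,) and outcome == (1,)

    def test_fixed_seed_reproducible(self, rng):
        m = random_small_model(rng, n_policies=1)
        seq1 = [step_process(np.random.default_rng(42), m, (0,), (0,))
                for _ in range(1)]
        seq2 = [step_process(np.random.default_rng(42), m, (0,), (0,))
                for _ in range(1)]
        assert seq1 == seq2

    def test_outcome_frequencies_match_likelihood(self):
        A = np.array([[0.3, 0.9], [0.7, 0.1]])
        m = DiscreteModel(A=[A], B=[np.eye(2)[:, :, None]],
                          D=[np.full(2, 0.5)], T=1)
        rng = np.random.default_rng(7)
        n = 10_000
        draws = np.array([sample_outcome(rng, m, (0,))[0] for _ in range(n)])
        p = 0.3
        sigma = np.sqrt(p * (1 - p) / n)
        assert abs((draws == 0).mean() - p) < 3 * sigma


class TestRunTrial:
    def test_posterior_tracks_deterministic_world(self):
        n = 3
        m = DiscreteModel(A=[np.eye(n)], B=[cycle_B(n)[:, :, None]],
                          D=[np.eye(n)[0]], T=3)
        rec = run_trial(m, m, seed=0, scheme="fixed_point")
        for t, belief in enumerate(rec.beliefs):
            assert belief.bma[0][t].argmax() == rec.true_states[t][0]

    def test_one_action_selection_per_epoch(self, rng):
        m = random_small_model(rng, T=4)
        rec = run_trial(m, m, seed=1)
        assert len(rec.actions) == 4
        assert len(rec.outcomes) == 4

    def test_preferences_drive_action_toward_goal(self):
        # two states, fully controllable; preferring outcome 1 must select
        # the action that moves to state 1 and reduce outcome risk
        n = 2
        B = np.zeros((n, n, 2))
        B[0, :, 0] = 1.0
        B[1, :, 1] = 1.0
        C = np.array([np.log(0.05), np.log(0.95)])
        policies = np.array([[[0], [0]], [[1], [1]]]).transpose(1, 0, 2)
        m = DiscreteModel(A=[np.eye(n)], B=[B], D=[np.eye(n)[0]], T=3,
                          C=[C], policies=policies, control_factors=(0,))
        rec = run_trial(m, m, seed=3)
        assert all(a == (1,) for a in rec.actions[:-1])
        assert rec.true_states[-1][0] == 1
        # risk of the predicted final outcome fell below the initial risk
        pref = softmax(C)

        def risk(o):
            return float(o @ (log_stable(o) - log_stable(pref)))

        o_first = rec.beliefs[0].bma[0][0] @ np.eye(n)
        o_last = rec.beliefs[-1].bma[0][-1] @ np.eye(n)
        assert risk(o_last) < risk(o_first)


class TestDeepMessages:
    def test_descending_onehot_bma_selects_column(self, rng):
        D = normalize_columns(rng.random((3, 4)) + 0.1)
        np.testing.assert_allclose(descending_message(D, np.eye(4)[2]),
                                   D[:, 2], atol=1e-12)

    def test_descending_uniform_bma_averages_rows(self, rng):
        D = normalize_columns(rng.random((3, 4)) + 0.1)
        np.testing.assert_allclose(descending_message(D, np.full(4, 0.25)),
                                   D.mean(axis=1), atol=1e-12)

    def test_descending_identity_returns_bma(self):
        bma = np.array([0.2, 0.3, 0.5])
        np.testing.assert_allclose(descending_message(np.eye(3), bma), bma)

    def test_ascending_matrix_product_example(self):
        D = np.array([[0.9, 0.1], [0.1, 0.9]])
        ev = ascending_message(D, np.array([0.8, 0.2]))
        np.testing.assert_allclose(ev, np.log([0.74, 0.26]), atol=1e-9)

    def test_ascending_uniform_inputs_are_flat(self):
        ev = ascending_message(np.full((2, 2), 0.5), np.full(2, 0.5))
        assert np.ptp(ev) < 1e-12

    def test_ascending_onehot_columns_peak_correctly(self):
        D = np.eye(3)
        ev = ascending_message(D, np.eye(3)[1])
        assert ev.argmax() == 1


class TestRunDeep:
    def _higher(self, T=1, n=2):
        return DiscreteModel(A=[], B=[np.eye(n)[:, :, None]],
                             D=[np.full(n, 1 / n)], T=T)

    def test_flattening_oracle_on_toy(self):
        # one-hot interface: deep higher posterior equals the posterior of
        # the equivalent flattened single-level model
        A_low = np.array([[0.9, 0.1], [0.1, 0.9]])
        A_obs = np.array([[1.0, 1.0], [0.0, 0.0]])  # observation fixed at 0
        higher = self._higher()
        hp = DiscreteModel(A=[], B=[np.eye(2)[:, :, None]],
                           D=[np.eye(2)[0]], T=1)
        lower = DiscreteModel(A=[A_low], B=[np.eye(2)[:, :, None]],
                              D=[np.full(2, 0.5)], T=1)
        lowp = DiscreteModel(A=[A_obs], B=[np.eye(2)[:, :, None]],
                             D=[np.eye(2)[0]], T=1)
        rec = run_deep(higher, lower, [(0, np.eye(2))], hp, lowp,
                       seed=0, scheme="fixed_point")
        # flattened: posterior over higher state given the lower outcome 0
        lik = A_low[0] / A_low[0].sum()
        expected = lik * 0.5
        expected /= expected.sum()
        np.testing.assert_allclose(rec.higher.beliefs[0].bma[0][0],
                                   expected, atol=1e-8)

    def test_lower_level_runs_T_epochs_per_higher_transition(self, rng):
        higher = self._higher()
        hp = DiscreteModel(A=[], B=[np.eye(2)[:, :, None]],
                           D=[np.eye(2)[0]], T=1)
        lower = random_small_model(rng, n_states=2, T=3, n_policies=1)
        rec = run_deep(higher, lower, [(0, np.eye(2))], hp, lower, seed=0)
        assert len(rec.lower) == 1
        assert len(rec.lower[0].beliefs) == 3

    def test_severed_ascending_leaves_prior(self):
        higher = self._higher()
        hp = DiscreteModel(A=[], B=[np.eye(2)[:, :, None]],
                           D=[np.eye(2)[0]], T=1)
        lower = DiscreteModel(A=[np.eye(2)], B=[np.eye(2)[:, :, None]],
                              D=[np.full(2, 0.5)], T=1)
        rec = run_deep(higher, lower, [(0, np.eye(2))], hp, lower,
                       seed=0, ascend=False, scheme="fixed_point")
        np.testing.assert_allclose(rec.higher.beliefs[0].bma[0][0],
                                   higher.D[0], atol=1e-8)

    def test_identity_interface_reproduces_single_level_trial(self):
        # deterministic world so that both schedulers see identical data
        n = 3
        A = normalize_columns(np.array([[0.7, 0.2, 0.1],
                                        [0.2, 0.6, 0.2],
                                        [0.1, 0.2, 0.7]]))
        B = cycle_B(n)[:, :, None]
        D = np.full(n, 1 / n)
        single = DiscreteModel(A=[A], B=[B], D=[D], T=3)
        proc = DiscreteModel(A=[np.eye(n)], B=[B], D=[np.eye(n)[0]], T=3)
        rec_single = run_trial(single, proc, seed=0, scheme="fixed_point",
                               tol=1e-12)

        higher = DiscreteModel(A=[], B=[B], D=[D], T=3)
        hproc = DiscreteModel(A=[], B=[B], D=[np.eye(n)[0]], T=3)
        lower = DiscreteModel(A=[A], B=[np.eye(n)[:, :, None]],
                              D=[np.full(n, 1 / n)], T=1)
        lproc = DiscreteModel(A=[np.eye(n)], B=[np.eye(n)[:, :, None]],
                              D=[np.eye(n)[0]], T=1)
        rec_deep = run_deep(higher, lower, [(0, np.eye(n))], hproc, lproc,
                            seed=0, scheme="fixed_point", tol=1e-12)
        for t in range(3):
            np.testing.assert_allclose(
                rec_deep.higher.beliefs[t].bma[0][t],
                rec_single.beliefs[t].bma[0][t], atol=1e-6)
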