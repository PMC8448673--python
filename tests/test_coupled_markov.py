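import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import binom, chisquare

from vasoionics import (
    CoupledMarkovParams,
    LevelSequence,
    TransitionMatrix,
    build_transition_matrix,
    fit_params,
    loglik,
    simulate_chain,
    stationary_distribution,
)
from vasoionics.coupled_markov import transition_counts

from conftest import enumerate_uncoupled_row


class TestParams:
    def test_valid(self):
        p = CoupledMarkovParams(2, 0.3, 0.9, 0.95)
        assert p.p_inf == pytest.approx(0.05 / 0.15)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(n_channels=0, kappa=0.5, rho=0.5, sigma_c=0.5),
            dict(n_channels=2, kappa=-0.1, rho=0.5, sigma_c=0.5),
            dict(n_channels=2, kappa=1.1, rho=0.5, sigma_c=0.5),
            dict(n_channels=2, kappa=0.5, rho=1.0, sigma_c=1.0),
            dict(n_channels=2, kappa=0.5, rho=0.5, sigma_c=0.5, unitary_current=0.0),
            dict(n_channels=2, kappa=0.5, rho=0.5, sigma_c=0.5, dt=0.0),
        ],
    )
    def test_invalid(self, kwargs):
        with pytest.raises(ValueError):
            CoupledMarkovParams(**kwargs)


class TestBuildTransitionMatrix:
    def test_n1_mixture_collapses(self):
        # one channel cannot be coupled to itself
        for kappa in (0.0, 0.3, 1.0):
            t = build_transition_matrix(CoupledMarkovParams(1, kappa, 0.6, 0.8)).probs
            np.testing.assert_allclose(t, [[0.8, 0.2], [0.4, 0.6]])

    def test_n2_fully_coupled_row0(self):
        t = build_transition_matrix(CoupledMarkovParams(2, 1.0, 0.6, 0.8)).probs
        np.testing.assert_allclose(t[0], [0.8, 0.0, 0.2])

    def test_n2_uncoupled_vs_enumeration(self, uncoupled_n2):
        t = build_transition_matrix(uncoupled_n2).probs
        for k in range(3):
            oracle = enumerate_uncoupled_row(2, k, 0.6, 0.8)
            np.testing.assert_allclose(t[k], oracle, atol=1e-14)
        # frozen expected row from the enumeration oracle
        np.testing.assert_allclose(t[1], [0.32, 0.56, 0.12], atol=1e-14)

    @pytest.mark.parametrize("n", [1, 2, 3, 4])
    def test_uncoupled_matches_enumeration_all_n(self, n):
        rho, sig = 0.7, 0.85
        t = build_transition_matrix(CoupledMarkovParams(n, 0.0, rho, sig)).probs
        for k in range(n + 1):
            np.testing.assert_allclose(
                t[k], enumerate_uncoupled_row(n, k, rho, sig), atol=1e-12
            )

    @given(
        n=st.integers(1, 4),
        kappa=st.floats(0.0, 1.0),
        rho=st.floats(0.01, 0.99),
        sig=st.floats(0.01, 0.99),
    )
    @settings(max_examples=60, deadline=None)
    def test_row_stochastic(self, n, kappa, rho, sig):
        t = build_transition_matrix(CoupledMarkovParams(n, kappa, rho, sig)).probs
        assert np.all(t >= 0)
        np.testing.assert_allclose(t.sum(axis=1), 1.0, atol=1e-12)

    def test_coupled_rows_only_extremes(self):
        t = build_transition_matrix(CoupledMarkovParams(3, 1.0, 0.6, 0.8)).probs
        assert np.all(t[:, 1:-1] == 0.0)


class TestStationaryDistribution:
    def test_two_state_closed_form(self):
        t = build_transition_matrix(CoupledMarkovParams(1, 0.0, 0.6, 0.8))
        pi = stationary_distribution(t)
        assert pi[1] == pytest.approx((1 - 0.8) / ((1 - 0.8) + (1 - 0.6)))
        assert pi[1] == pytest.approx(1.0 / 3.0)

    def test_fixed_point_identity(self):
        for params in [
            CoupledMarkovParams(3, 0.4, 0.9, 0.7),
            CoupledMarkovParams(2, 0.0, 0.5, 0.5),
            CoupledMarkovParams(4, 0.95, 0.8, 0.9),
        ]:
            t = build_transition_matrix(params)
            pi = stationary_distribution(t)
            assert np.max(np.abs(pi @ t.probs - pi)) < 1e-10
            assert pi.sum() == pytest.approx(1.0)

    def test_independent_binomial(self):
        # N=3, per-channel p_inf = 0.25 -> pi is Binomial(3, 0.25)
        params = CoupledMarkovParams(3, 0.0, 0.7, 0.9)
        assert params.p_inf == pytest.approx(0.25)
        pi = stationary_distribution(build_transition_matrix(params))
        np.testing.assert_allclose(pi, binom.pmf(np.arange(4), 3, 0.25), atol=1e-10)

    def test_reducible_flagged(self):
        probs = np.array([[1.0, 0.0, 0.0], [0.5, 0.0, 0.5], [0.0, 0.0, 1.0]])
        with pytest.warns(RuntimeWarning, match="reducible"):
            pi = stationary_distribution(TransitionMatrix(probs))
        assert pi.sum() == pytest.approx(1.0)
        assert pi[1] == 0.0


class TestSimulateChain:
    def test_unison_never_interior(self):
        params = CoupledMarkovParams(3, 1.0, 0.9, 0.8)
        seq = simulate_chain(params, 5000, seed=7, initial_level=0)
        assert set(np.unique(seq.levels)) <= {0, 3}

    def test_seed_determinism(self):
        params = CoupledMarkovParams(2, 0.3, 0.9, 0.95)
        a = simulate_chain(params, 2000, seed=11)
        b = simulate_chain(params, 2000, seed=11)
        np.testing.assert_array_equal(a.levels, b.levels)
        c = simulate_chain(params, 2000, seed=12)
        assert not np.array_equal(a.levels, c.levels)

    def test_occupancy_matches_stationary_3se(self):
        # kappa=0, N=2: occupancy within 3 batch-means MC standard errors
        params = CoupledMarkovParams(2, 0.0, 0.9, 0.95)
        n_steps = 1_000_000
        seq = simulate_chain(params, n_steps, seed=3)
        pi = stationary_distribution(build_transition_matrix(params))
        onehot = np.eye(3)[seq.levels]
        n_batches = 100
        batches = onehot[: n_steps - n_steps % n_batches].reshape(
            n_batches, -1, 3
        ).mean(axis=1)
        se = batches.std(axis=0, ddof=1) / np.sqrt(n_batches)
        np.testing.assert_array_less(np.abs(onehot.mean(axis=0) - pi), 3 * se)

    def test_chi2_goodness_of_fit_thinned(self):
        # thin to ~independent samples so the chi^2 sampling model applies
        params = CoupledMarkovParams(2, 0.2, 0.7, 0.8)
        seq = simulate_chain(params, 1_000_000, seed=5)
        thinned = seq.levels[::20]
        pi = stationary_distribution(build_transition_matrix(params))
        observed = np.bincount(thinned, minlength=3)
        stat, p = chisquare(observed, pi * thinned.size)
        assert p > 0.01

    def test_bad_args(self):
        params = CoupledMarkovParams(2, 0.0, 0.5, 0.5)
        with pytest.raises(ValueError):
            simulate_chain(params, 0, seed=1)
        with pytest.raises(ValueError):
            simulate_chain(params, 10, seed=1, initial_level=5)


class TestLoglik:
    def test_two_sample_exact(self):
        params = CoupledMarkovParams(2, 0.3, 0.9, 0.95)
        t = build_transition_matrix(params).probs
        seq = LevelSequence(np.array([1, 2]), params.dt, 2)
        assert loglik(seq, params) == pytest.approx(np.log(t[1, 2]))

    def test_ten_step_product_oracle(self):
        params = CoupledMarkovParams(2, 0.25, 0.8, 0.9)
        t = build_transition_matrix(params).probs
        levels = np.array([0, 1, 1, 2, 2, 1, 0, 0, 1, 2])
        seq = LevelSequence(levels, params.dt, 2)
        expected = sum(
            np.log(t[a, b]) for a, b in zip(levels[:-1], levels[1:])
        )
        assert loglik(seq, params) == pytest.approx(expected)

    def test_parameter_label_swap_changes_loglik(self):
        levels = np.array([0, 0, 0, 1, 0, 0, 1, 0, 0, 0])
        seq = LevelSequence(levels, 1e-4, 1)
        a = loglik(seq, CoupledMarkovParams(1, 0.0, 0.9, 0.6))
        b = loglik(seq, CoupledMarkovParams(1, 0.0, 0.6, 0.9))
        assert a != pytest.approx(b)

    def test_forbidden_transition_floored(self):
        params = CoupledMarkovParams(2, 1.0, 0.9, 0.8)  # interior level unreachable
        seq = LevelSequence(np.array([0, 1]), params.dt, 2)
        with pytest.warns(RuntimeWarning, match="forbidden"):
            ll = loglik(seq, params)
        assert ll == pytest.approx(-700.0)

    def test_too_short(self):
        with pytest.raises(ValueError):
            loglik(LevelSequence(np.array([1]), 1e-4, 2), CoupledMarkovParams(2, 0, 0.5, 0.5))


class TestFitParams:
    def test_recovery_round_trip(self):
        truth = CoupledMarkovParams(2, 0.30, 0.90, 0.95)
        seq = simulate_chain(truth, 100_000, seed=1)
        fit = fit_params(seq, 2)
        assert abs(fit.params.kappa - 0.30) < 0.05
        assert abs(fit.params.rho - 0.90) < 0.05
        assert abs(fit.params.sigma_c - 0.95) < 0.05
        assert fit.converged

    def test_uncoupled_boundary_recovery(self):
        truth = CoupledMarkovParams(2, 0.0, 0.9, 0.95)
        seq = simulate_chain(truth, 100_000, seed=2)
        fit = fit_params(seq, 2)
        assert fit.params.kappa <= 0.05

    def test_fit_improves_on_perturbed_truth(self):
        truth = CoupledMarkovParams(2, 0.30, 0.90, 0.95)
        seq = simulate_chain(truth, 20_000, seed=4)
        fit = fit_params(seq, 2)
        wrong = CoupledMarkovParams(2, 0.6, 0.7, 0.7)
        assert fit.loglik >= loglik(seq, wrong)
        assert fit.loglik >= loglik(seq, truth) - 1e-6

    def test_all_zeros_degenerate(self):
        seq = LevelSequence(np.zeros(500, dtype=int), 1e-4, 2)
        fit = fit_params(seq, 2)
        assert fit.degenerate
        assert fit.params.sigma_c == pytest.approx(1.0)

    def test_all_open_degenerate(self):
        seq = LevelSequence(np.full(500, 2), 1e-4, 2)
        fit = fit_params(seq, 2)
        assert fit.degenerate
        assert fit.params.rho == pytest.approx(1.0)


class TestSerialization:
    def test_level_sequence_json_round_trip(self):
        seq = LevelSequence(np.array([0, 1, 2, 1]), 1e-4, 2)
        back = LevelSequence.from_json(seq.to_json())
        np.testing.assert_array_equal(back.levels, seq.levels)
        assert back.dt == seq.dt and back.n_channels == seq.n_channels

    def test_params_json_round_trip(self):
        p = CoupledMarkovParams(3, 0.2, 0.8, 0.9, 1.5, 5e-5)
        assert CoupledMarkovParams.from_json(p.to_json()) == p

    def test_matrix_csv(self, tmp_path):
        t = build_transition_matrix(CoupledMarkovParams(2, 0.3, 0.8, 0.9))
        path = tmp_path / "t.csv"
        t.to_csv(path)
        np.testing.assert_allclose(np.loadtxt(path, delimiter=","), t.probs)
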