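"""Fermi imitation, fixation probabilities and the embedded Markov chain."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import expit

from ircom import (
    EvoParams,
    GameParams,
    IRParams,
    build_payoff_matrix,
    finite_pop_payoffs,
    fixation_matrix,
    fixation_probability,
    imitation_probability,
    small_mutation_transition_matrix,
    stationary_distribution,
    transition_graph,
)


def birth_death_fixation(pi: np.ndarray, N: int, beta: float) -> float:
    """Brute-force oracle: absorption probability of the explicit chain.

    Builds the full (N+1)-state birth-death chain with hopping rates
    ``T+(k) = (N-k)/N * k/(N-1) * Fermi`` and solves the linear absorption
    system directly, independently of the closed-form product formula.
    Solved in 50-digit arithmetic: the system's conditioning grows like
    ``exp(beta * sum |df|)`` and float64 cannot reach 1e-8 under strong
    selection.
    """
    import mpmath as mp

    k = np.arange(1, N)
    f_a = ((k - 1) * pi[0, 0] + (N - k) * pi[0, 1]) / (N - 1)
    f_b = (k * pi[1, 0] + (N - k - 1) * pi[1, 1]) / (N - 1)
    with mp.workdps(50):
        fermi_up = [1 / (1 + mp.e ** (-mp.mpf(beta) * (fa - fb))) for fa, fb in zip(f_a, f_b)]
        t_plus = [(N - kk) / mp.mpf(N) * kk / (N - 1) * p for kk, p in zip(k, fermi_up)]
        t_minus = [kk / mp.mpf(N) * (N - kk) / (N - 1) * (1 - p) for kk, p in zip(k, fermi_up)]
        # h(k) = P(absorb at N | start k); h(0)=0, h(N)=1
        n = N - 1
        A = mp.zeros(n)
        b = mp.zeros(n, 1)
        for i in range(n):
            A[i, i] = t_plus[i] + t_minus[i]
            if i > 0:
                A[i, i - 1] = -t_minus[i]
            if i < n - 1:
                A[i, i + 1] = -t_plus[i]
        b[n - 1] = t_plus[n - 1]
        h = mp.lu_solve(A, b)
        return float(h[0])


class TestFinitePopPayoffs:
    def test_constant_game(self):
        pi = np.full((2, 2), 1.7)
        for k in (1, 10, 99):
            f_a, f_b = finite_pop_payoffs(k, pi, 100)
            assert f_a == pytest.approx(1.7) and f_b == pytest.approx(1.7)

    def test_cooperators_vs_defectors_hand_arithmetic(self):
        # Donor game b=4, c=1: pi = [[3, -1], [4, 0]], N=100, k=50
        pi = np.array([[3.0, -1.0], [4.0, 0.0]])
        f_c, f_d = finite_pop_payoffs(50, pi, 100)
        assert f_c == pytest.approx((49 * 3 + 50 * (-1)) / 99)
        assert f_d == pytest.approx(50 * 4 / 99)

    def test_two_agents_only_cross_interact(self):
        pi = np.array([[5.0, 2.0], [7.0, 1.0]])
        f_a, f_b = finite_pop_payoffs(1, pi, 2)
        assert (f_a, f_b) == (2.0, 7.0)

    def test_k_out_of_range(self):
        with pytest.raises(ValueError):
            finite_pop_payoffs(0, np.eye(2), 10)


class TestImitationProbability:
    def test_neutral_drift(self):
        assert imitation_probability(3.0, -5.0, 0.0) == 0.5

    def test_equal_fitness(self):
        assert imitation_probability(2.0, 2.0, 7.3) == 0.5

    def test_deterministic_limit_no_overflow(self):
        assert imitation_probability(0.0, 100.0, 10.0) == pytest.approx(1.0, abs=1e-12)
        assert imitation_probability(100.0, 0.0, 10.0) == pytest.approx(0.0, abs=1e-12)

    @given(df=st.floats(-5, 5), beta=st.floats(0.01, 2))
    @settings(max_examples=100, derandomize=True)
    def test_monotone_in_fitness_difference(self, df, beta):
        p1 = imitation_probability(0.0, df, beta)
        p2 = imitation_probability(0.0, df + 1.0, beta)
        assert p2 > p1


class TestFixationProbability:
    def test_neutral_equals_one_over_n(self):
        pi = np.array([[3.0, -1.0], [4.0, 0.0]])
        evo = EvoParams(N=100, beta=0.0)
        assert fixation_probability(pi, evo) == pytest.approx(0.01, abs=0)

    def test_two_agents_single_step(self):
        pi = np.array([[3.0, -1.0], [4.0, 0.0]])
        evo = EvoParams(N=2, beta=0.5)
        f_a, f_b = finite_pop_payoffs(1, pi, 2)
        assert fixation_probability(pi, evo) == pytest.approx(
            float(imitation_probability(f_b, f_a, 0.5))
        )

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_birth_death_absorption(self, seed):
        prng = np.random.default_rng(seed)
        pi = prng.uniform(-3, 5, size=(2, 2))
        N = int(prng.integers(3, 31))
        beta = float(prng.uniform(0.05, 2.0))
        evo = EvoParams(N=N, beta=beta)
        assert fixation_probability(pi, evo) == pytest.approx(
            birth_death_fixation(pi, N, beta), abs=1e-10
        )

    def test_large_beta_no_overflow(self):
        pi = np.array([[0.0, -10.0], [10.0, 0.0]])
        rho = fixation_probability(pi, EvoParams(N=100, beta=50.0))
        assert 0.0 <= rho <= 1e-12  # doomed mutant, but finite arithmetic


class TestTransitionChain:
    def test_neutral_fixation_matrix(self, donor_game, ir_default):
        pm = build_payoff_matrix(donor_game, ir_default)
        rho = fixation_matrix(pm, EvoParams(N=100, beta=0.0))
        off = rho[~np.eye(6, dtype=bool)]
        assert np.all(off == 0.01)

    def test_hand_built_two_strategy_chain(self):
        rho = np.array([[np.nan, 0.2], [0.05, np.nan]])
        M = small_mutation_transition_matrix(rho)
        assert M == pytest.approx(np.array([[0.95, 0.05], [0.2, 0.8]]))

    def test_rows_sum_to_one_random(self, rng):
        q = 6
        rho = rng.uniform(0, 1, size=(q, q))
        M = small_mutation_transition_matrix(rho)
        assert M.sum(axis=1) == pytest.approx(np.ones(q))
        assert np.all(M >= 0)

    def test_uniform_neutral_offdiagonals(self):
        rho = np.full((4, 4), 1 / 50)
        M = small_mutation_transition_matrix(rho)
        off = M[~np.eye(4, dtype=bool)]
        assert np.all(off == pytest.approx(1 / (50 * 3)))


class TestStationaryDistribution:
    def test_neutral_is_uniform(self):
        M = small_mutation_transition_matrix(np.full((6, 6), 0.01))
        assert stationary_distribution(M) == pytest.approx(np.full(6, 1 / 6))

    def test_absorbing_direction(self):
        rho = np.array([[np.nan, 0.2], [0.0, np.nan]])
        sigma = stationary_distribution(small_mutation_transition_matrix(rho))
        assert sigma == pytest.approx([1.0, 0.0], abs=1e-12)

    def test_two_state_detailed_balance(self):
        rho = np.array([[np.nan, 0.2], [0.05, np.nan]])
        sigma = stationary_distribution(small_mutation_transition_matrix(rho))
        assert sigma == pytest.approx([0.8, 0.2])
        assert sigma[0] * rho[1, 0] == pytest.approx(sigma[1] * rho[0, 1])

    @pytest.mark.parametrize("seed", range(5))
    def test_fixed_point_random_chains(self, seed):
        prng = np.random.default_rng(seed)
        q = int(prng.integers(2, 8))
        M = prng.uniform(size=(q, q))
        M /= M.sum(axis=1, keepdims=True)
        sigma = stationary_distribution(M)
        assert np.max(np.abs(sigma @ M - sigma)) < 1e-10
        assert sigma.sum() == pytest.approx(1.0, abs=1e-10)
        assert np.all(sigma >= 0)

    def test_rejects_non_stochastic(self):
        with pytest.raises(ValueError):
            stationary_distribution(np.array([[0.5, 0.2], [0.3, 0.7]]))


class TestTransitionGraph:
    def test_neutral_graph_is_empty(self):
        rho = np.full((6, 6), 0.01)
        G = transition_graph(rho, EvoParams(N=100, beta=0.0))
        assert G.number_of_edges() == 0

    def test_edge_weight_in_neutral_units(self):
        rho = np.full((2, 2), 0.005)
        rho[0, 1] = 0.02  # strategy 0 invades resident 1 at twice neutral
        G = transition_graph(rho, EvoParams(N=100, beta=0.1), labels=["A", "B"])
        assert list(G.edges) == [("B", "A")]
        assert G.edges["B", "A"]["weight"] == pytest.approx(2.0)
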