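"""Finite-population stochastic dynamics in the small-mutation limit.

A well-mixed population of ``N`` imitators evolves by the pairwise
comparison (Fermi) rule: an agent with payoff ``f_A`` adopts the strategy of
a random other agent with payoff ``f_B`` with probability
``1 / (1 + exp(-beta (f_B - f_A)))``, where ``beta`` is the imitation
strength.  For rare mutations the population is monomorphic almost always,
and the dynamics reduce to a Markov chain over homogeneous states whose
transitions are single-mutant fixation probabilities; its stationary
distribution gives the long-run time spent in each strategy.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.special import expit, logsumexp

from .payoffs import PayoffMatrix

__all__ = [
    "EvoParams",
    "finite_pop_payoffs",
    "imitation_probability",
    "fixation_probability",
    "fixation_matrix",
    "small_mutation_transition_matrix",
    "stationary_distribution",
    "transition_graph",
]


@dataclass(frozen=True)
class EvoParams:
    """Population size ``N`` (>= 2) and imitation strength ``beta`` (>= 0)."""

    N: int = 100
    beta: float = 0.1

    def __post_init__(self) -> None:
        if int(self.N) != self.N or self.N < 2:
            raise ValueError(f"N must be an integer >= 2, got {self.N}")
        if self.beta < 0:
            raise ValueError(f"beta must be non-negative, got {self.beta}")


def finite_pop_payoffs(k, pi: np.ndarray, N: int):
    """Average payoffs of A- and B-players when ``k`` of ``N`` agents play A.

    Self-interaction is excluded: an A-player meets ``k - 1`` other A's and
    ``N - k`` B's among its ``N - 1`` possible partners.  ``pi`` is the 2x2
    payoff matrix ``[[pi_AA, pi_AB], [pi_BA, pi_BB]]``.  ``k`` may be a
    scalar or an array; the interior range ``1 <= k <= N - 1`` is required.
    """
    k = np.asarray(k, dtype=float)
    if np.any(k < 1) or np.any(k > N - 1):
        raise ValueError("k must satisfy 1 <= k <= N - 1")
    f_a = ((k - 1) * pi[0, 0] + (N - k) * pi[0, 1]) / (N - 1)
    f_b = (k * pi[1, 0] + (N - k - 1) * pi[1, 1]) / (N - 1)
    if f_a.ndim == 0:
        return float(f_a), float(f_b)
    return f_a, f_b


def imitation_probability(f_a, f_b, beta: float):
    """Fermi imitation probability ``[1 + exp(-beta (f_B - f_A))]^{-1}``.

    Overflow-safe for arbitrarily large ``|beta * (f_B - f_A)|``; returns
    exactly 0.5 at ``beta = 0`` (neutral drift).
    """
    if beta < 0:
        raise ValueError("beta must be non-negative")
    return expit(beta * (np.asarray(f_b, dtype=float) - np.asarray(f_a, dtype=float)))


def fixation_probability(pi: np.ndarray, evo: EvoParams) -> float:
    """Fixation probability of a single A-mutant among ``N - 1`` B-residents.

    Uses the birth-death closed form
    ``rho = [1 + sum_{i=1}^{N-1} prod_{j=1}^{i} exp(-beta (f_A(j) - f_B(j)))]^{-1}``
    evaluated in log-space (cumulative sums + logsumexp) so that large
    ``beta * N`` cannot overflow.  ``pi`` is the 2x2 payoff matrix with A as
    the first row.  At ``beta = 0`` the result is exactly ``1/N``.
    """
    N, beta = evo.N, evo.beta
    if beta == 0.0:
        return 1.0 / N
    j = np.arange(1, N)
    f_a, f_b = finite_pop_payoffs(j, np.asarray(pi, dtype=float), N)
    log_terms = np.cumsum(-beta * (f_a - f_b))
    # rho = exp(-logsumexp([0, cumsums]))
    return float(np.exp(-logsumexp(np.concatenate(([0.0], log_terms)))))


def fixation_matrix(payoffs: PayoffMatrix, evo: EvoParams) -> np.ndarray:
    """Pairwise fixation probabilities ``rho[i, j]`` (mutant i in resident j).

    The diagonal is set to ``nan`` (a mutant of the resident strategy is not
    a meaningful event in the small-mutation chain).
    """
    q = len(payoffs.labels)
    rho = np.full((q, q), np.nan)
    v = payoffs.values
    for i in range(q):
        for j in range(q):
            if i == j:
                continue
            pi = np.array([[v[i, i], v[i, j]], [v[j, i], v[j, j]]])
            rho[i, j] = fixation_probability(pi, evo)
    return rho


def small_mutation_transition_matrix(rho: np.ndarray, q: int | None = None) -> np.ndarray:
    """Embedded Markov chain over homogeneous states.

    Off-diagonal entries are ``M[i, j] = rho[j, i] / (q - 1)`` -- the chance
    that the single mutant arising in an i-population is of strategy j times
    its fixation probability -- and the diagonal absorbs the remainder so
    rows sum to 1.
    """
    rho = np.asarray(rho, dtype=float)
    if q is None:
        q = rho.shape[0]
    if q < 2 or rho.shape != (q, q):
        raise ValueError("need a q x q fixation matrix with q >= 2")
    M = rho.T.copy() / (q - 1)
    np.fill_diagonal(M, 0.0)
    np.fill_diagonal(M, 1.0 - M.sum(axis=1))
    return M


def stationary_distribution(M: np.ndarray) -> np.ndarray:
    """Stationary distribution of a row-stochastic matrix.

    Normalized eigenvector of ``M.T`` for the eigenvalue closest to 1, with
    tiny negative entries clipped; falls back to a null-space linear solve
    when the eigenproblem is ill-conditioned.
    """
    M = np.asarray(M, dtype=float)
    q = M.shape[0]
    if M.shape != (q, q) or np.any(M < -1e-12) or not np.allclose(M.sum(axis=1), 1.0, atol=1e-8):
        raise ValueError("M must be row-stochastic")
    vals, vecs = np.linalg.eig(M.T)
    idx = int(np.argmin(np.abs(vals - 1.0)))
    sigma = np.real(vecs[:, idx])
    if sigma.sum() < 0:
        sigma = -sigma
    sigma = sigma / sigma.sum()
    sigma[(sigma < 0) & (sigma > -1e-9)] = 0.0
    if np.any(sigma < 0) or abs(vals[idx] - 1.0) > 1e-6:
        # null-space solve: (M.T - I) sigma = 0 with sum(sigma) = 1
        A = np.vstack([M.T - np.eye(q), np.ones(q)])
        b = np.concatenate([np.zeros(q), [1.0]])
        sigma, *_ = np.linalg.lstsq(A, b, rcond=None)
        sigma = np.clip(sigma, 0.0, None)
    return sigma / sigma.sum()


def transition_graph(rho: np.ndarray, evo: EvoParams, labels=None) -> nx.DiGraph:
    """Directed graph of stronger-than-neutral invasions.

    An edge runs from resident ``i`` to invader ``j`` iff
    ``rho[j, i] > 1/N``; the edge weight is the fixation probability
    expressed as a multiple of the neutral probability ``rho_N = 1/N``.
    """
    rho = np.asarray(rho, dtype=float)
    q = rho.shape[0]
    if labels is None:
        labels = [str(i) for i in range(q)]
    rho_n = 1.0 / evo.N
    G = nx.DiGraph()
    G.add_nodes_from(labels)
    for i in range(q):
        for j in range(q):
            if i != j and rho[j, i] > rho_n:
                G.add_edge(labels[i], labels[j], weight=rho[j, i] / rho_n, rho=rho[j, i])
    return G


def graph_to_dot(G: nx.DiGraph) -> str:
    """Render the invasion graph as Graphviz DOT text."""
    lines = ["digraph transitions {"]
    for node in G.nodes:
        lines.append(f'  "{node}";')
    for u, v, data in G.edges(data=True):
        lines.append(f'  "{u}" -> "{v}" [label="{data["weight"]:.2f} rho_N"];')
    lines.append("}")
    return "\n".join(lines)
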