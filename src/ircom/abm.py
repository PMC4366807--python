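"""Agent-based Monte-Carlo oracle for the analytic model.

Two independent stochastic checks live here:

* :func:`interaction_sample` / :func:`sample_interactions` realize single
  one-shot encounters event by event -- drawing IRCOM's confidence,
  resolving proposals, acceptances, moves and the eps/delta payments -- so
  their sample mean is an unbiased estimator of the closed-form
  :func:`~ircom.payoffs.pair_payoff`.

* :func:`abm_run` simulates the full imitation-plus-mutation process
  (asynchronous pairwise-comparison updates at exploration rate ``mu``) and
  reports time-averaged strategy frequencies, which converge to the
  small-mutation stationary distribution as ``mu -> 0``.

Payoffs inside the population simulation are the exact expected payoffs
against the current composition (self-interaction excluded) rather than
resampled games: the expectation is identical and the variance far lower.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .payoffs import (
    STRATEGIES,
    STRATEGY_TRAITS,
    GameParams,
    IRParams,
    build_payoff_matrix,
)

__all__ = ["ABMConfig", "ABMResult", "abm_run", "interaction_sample", "sample_interactions"]


# ---------------------------------------------------------------------------
# Single-encounter sampler
# ---------------------------------------------------------------------------


def _side(strategy: str, opponent: str, n: int, ir: IRParams, rng: np.random.Generator):
    """Resolve one side's behaviour for ``n`` independent encounters.

    Returns boolean arrays ``(proposes, coop_in_deal, coop_plain)``.
    """
    traits = STRATEGY_TRAITS[strategy]
    if strategy == "IRCOM":
        if opponent == "COMP":
            # COMP proposes first; IRCOM simply accepts and cooperates.
            false = np.zeros(n, dtype=bool)
            return false, ~false, ~false
        x = rng.random(n)
        commit = x <= ir.theta
        correct = rng.random(n) < np.minimum(ir.r * x, 1.0)
        opp_intends = STRATEGY_TRAITS[opponent].intends_cooperate
        # acting on the prediction means matching the predicted intention
        rely_coop = correct if opp_intends else ~correct
        coop_in_deal = commit | rely_coop  # proposer cooperates; acceptor follows its read
        return commit, coop_in_deal, rely_coop
    proposes = np.full(n, traits.proposes == "always")
    coop_in_deal = np.full(n, traits.deal_action == "C")
    coop_plain = np.full(n, traits.plain_action == "C")
    return proposes, coop_in_deal, coop_plain


def sample_interactions(
    row: str,
    col: str,
    g: GameParams,
    ir: IRParams,
    rng: np.random.Generator,
    n: int,
    return_actions: bool = False,
):
    """Realized payoffs of ``n`` independent ``row`` vs ``col`` encounters.

    With ``return_actions=True`` also returns the two boolean cooperation
    arrays (entries are meaningful only for encounters where the game was
    actually played; a declined deal plays no game).
    """
    for label in (row, col):
        if label not in STRATEGIES:
            raise KeyError(f"unknown strategy label {label!r}")
    prop_r, deal_r, plain_r = _side(row, col, n, ir, rng)
    prop_c, deal_c, plain_c = _side(col, row, n, ir, rng)

    any_prop = prop_r | prop_c
    # arrangement cost: split when both propose, full for a sole proposer
    eps_r = np.where(prop_r, np.where(prop_c, g.eps / 2.0, g.eps), 0.0)
    eps_c = np.where(prop_c, np.where(prop_r, g.eps / 2.0, g.eps), 0.0)

    # only D declines proposals; a declined deal means no game is played
    declined = (prop_r & np.full(n, not STRATEGY_TRAITS[col].accepts)) | (
        prop_c & np.full(n, not STRATEGY_TRAITS[row].accepts)
    )
    deal = any_prop & ~declined

    coop_r = np.where(deal, deal_r, plain_r)
    coop_c = np.where(deal, deal_c, plain_c)

    base_r = np.where(
        coop_r, np.where(coop_c, g.R, g.S), np.where(coop_c, g.T, g.P)
    )
    base_c = np.where(
        coop_c, np.where(coop_r, g.R, g.S), np.where(coop_r, g.T, g.P)
    )
    played = ~any_prop | deal
    pay_r = np.where(played, base_r, 0.0) - eps_r
    pay_c = np.where(played, base_c, 0.0) - eps_c

    # compensation: a committed defector pays delta to the co-player
    transfer = deal & (coop_r != coop_c)
    pay_r = pay_r + np.where(transfer & ~coop_c, g.delta, 0.0) - np.where(
        transfer & ~coop_r, g.delta, 0.0
    )
    pay_c = pay_c + np.where(transfer & ~coop_r, g.delta, 0.0) - np.where(
        transfer & ~coop_c, g.delta, 0.0
    )
    if return_actions:
        return pay_r, pay_c, coop_r & played, coop_c & played
    return pay_r, pay_c


def interaction_sample(
    row: str, col: str, g: GameParams, ir: IRParams, rng: np.random.Generator
) -> tuple[float, float]:
    """One realized encounter; expectation over draws equals ``pair_payoff``."""
    pr, pc = sample_interactions(row, col, g, ir, rng, 1)
    return float(pr[0]), float(pc[0])


# ---------------------------------------------------------------------------
# Population simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ABMConfig:
    """Configuration of the imitation-plus-mutation simulation.

    ``steps`` counts asynchronous update events (one focal agent each);
    ``burn_in`` events are discarded before time-averaging (default: 10% of
    ``steps``).  ``initial_composition`` gives counts per strategy in
    canonical order and must sum to ``N`` (default: as even as possible).
    """

    N: int = 100
    beta: float = 0.1
    mu: float = 1e-3
    steps: int = 1_000_000
    burn_in: int | None = None
    seed: int = 0
    initial_composition: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.mu < 1.0):
            raise ValueError(f"mu must lie in (0, 1), got {self.mu}")
        burn = self.effective_burn_in
        if not (self.steps > burn >= 0):
            raise ValueError("need steps > burn_in >= 0")
        if self.initial_composition is not None:
            comp = self.initial_composition
            if len(comp) != len(STRATEGIES) or any(c < 0 for c in comp) or sum(comp) != self.N:
                raise ValueError(
                    f"initial_composition must be {len(STRATEGIES)} non-negative "
                    f"counts summing to N={self.N}"
                )

    @property
    def effective_burn_in(self) -> int:
        return self.steps // 10 if self.burn_in is None else self.burn_in


@dataclass(frozen=True)
class ABMResult:
    """Time-averaged strategy frequencies and homogeneous-state visits."""

    frequencies: np.ndarray
    homogeneous_visits: np.ndarray
    seed: int
    labels: tuple[str, ...] = STRATEGIES
    config: ABMConfig | None = field(default=None, compare=False)

    def as_dict(self) -> dict[str, float]:
        return {s: float(f) for s, f in zip(self.labels, self.frequencies)}


def _even_composition(N: int, q: int) -> list[int]:
    base, extra = divmod(N, q)
    return [base + (1 if i < extra else 0) for i in range(q)]


def abm_run(cfg: ABMConfig, g: GameParams, ir: IRParams) -> ABMResult:
    """Simulate the finite-population imitation process.

    Each update event picks a focal agent uniformly; with probability ``mu``
    it explores (adopts a uniformly random strategy, possibly its current
    one), otherwise it picks a distinct model agent uniformly and imitates
    with the Fermi probability computed from expected payoffs against the
    current composition.  Fully reproducible from ``cfg.seed``.

    While the population is homogeneous, imitation events cannot change the
    state, so the simulation jumps directly to the next mutation event (a
    geometric number of events ahead) -- an exact acceleration, since each
    event mutates with probability ``mu`` independently of the state.
    Time averages weight every post-update event after burn-in equally.
    """
    q = len(STRATEGIES)
    N, beta, mu = cfg.N, cfg.beta, cfg.mu
    P = build_payoff_matrix(g, ir).values.tolist()
    counts = list(
        cfg.initial_composition
        if cfg.initial_composition is not None
        else _even_composition(N, q)
    )
    # gsum[s] = sum_t counts[t] * P[s][t]; updated incrementally
    gsum = [sum(counts[t] * P[s][t] for t in range(q)) for s in range(q)]
    inv = 1.0 / (N - 1)
    exp, log = math.exp, math.log
    log1m_mu = log(1.0 - mu)

    rng = np.random.default_rng(cfg.seed)
    chunk = 1 << 16
    buf = rng.random(chunk).tolist()
    bi = 0

    burn = cfg.effective_burn_in
    steps = cfg.steps
    acc = [0.0] * q
    visits = [0] * q

    def record(ev_lo: int, ev_hi: int) -> None:
        """Credit events with indices in [ev_lo, ev_hi) to the current state."""
        n = min(ev_hi, steps) - max(ev_lo, burn)
        if n <= 0:
            return
        for a in range(q):
            if counts[a]:
                acc[a] += n * counts[a]
                if counts[a] == N:
                    visits[a] += n

    ev = 0
    while ev < steps:
        mono = -1
        for s in range(q):
            if counts[s] == N:
                mono = s
                break
        if mono >= 0:
            # geometric jump: events until (and including) the next mutation
            if bi >= chunk:
                buf = rng.random(chunk).tolist()
                bi = 0
            u0 = buf[bi]
            bi += 1
            gap = int(log(u0 if u0 > 0.0 else 5e-324) / log1m_mu) + 1
            if ev + gap > steps:
                record(ev, steps)
                break
            record(ev, ev + gap - 1)  # unchanged through the pre-mutation events
            ev += gap
            if bi >= chunk:
                buf = rng.random(chunk).tolist()
                bi = 0
            new = int(buf[bi] * q)
            bi += 1
            if new >= q:
                new = q - 1
            if new != mono:
                counts[mono] -= 1
                counts[new] += 1
                for a in range(q):
                    gsum[a] += P[a][new] - P[a][mono]
            record(ev - 1, ev)  # the mutation event itself, post-update
            continue

        if bi + 4 > chunk:
            buf = rng.random(chunk).tolist()
            bi = 0
        u0 = buf[bi]
        u1 = buf[bi + 1]
        u2 = buf[bi + 2]
        u3 = buf[bi + 3]
        bi += 4
        # focal strategy sampled proportionally to counts
        target = u0 * N
        cum = 0.0
        for s in range(q):
            cum += counts[s]
            if target < cum:
                break
        if u1 < mu:
            new = int(u2 * q)
            if new >= q:
                new = q - 1
            if new != s:
                counts[s] -= 1
                counts[new] += 1
                for a in range(q):
                    gsum[a] += P[a][new] - P[a][s]
        else:
            # model agent uniform among the other N - 1
            target = u2 * (N - 1)
            cum = 0.0
            for t in range(q):
                cum += counts[t] - (1 if t == s else 0)
                if target < cum:
                    break
            if t != s:
                f_s = (gsum[s] - P[s][s]) * inv
                f_t = (gsum[t] - P[t][t]) * inv
                arg = beta * (f_t - f_s)
                if arg > 700.0:
                    p = 1.0
                elif arg < -700.0:
                    p = 0.0
                else:
                    p = 1.0 / (1.0 + exp(-arg))
                if u3 < p:
                    counts[s] -= 1
                    counts[t] += 1
                    for a in range(q):
                        gsum[a] += P[a][t] - P[a][s]
        ev += 1
        record(ev - 1, ev)

    recorded = steps - burn
    freq = np.asarray(acc, dtype=float) / (recorded * N)
    return ABMResult(
        frequencies=freq,
        homogeneous_visits=np.asarray(visits),
        seed=cfg.seed,
        config=cfg,
    )
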