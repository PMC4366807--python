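"""Closed-form expected payoffs for commitment strategies in the one-shot PD.

Six strategies interact in a Donor-game Prisoner's Dilemma (T = b, R = b - c,
P = 0, S = -c) extended with a costly commitment device: a proposer pays an
arrangement cost ``eps`` to set up a deal, and a player who commits but then
defects owes the co-player a compensation ``delta``.

Strategies (canonical order, used for all matrices):

* ``IRCOM`` -- predicts the co-player's intention with confidence
  ``x ~ U(0, 1)`` and accuracy ``y = min(r * x, 1)``.  If ``x > theta`` it
  acts on the prediction (cooperate with predicted cooperators, defect
  against predicted defectors); otherwise it proposes a commitment and
  cooperates if the proposal is accepted, refusing to play if it is declined.
* ``COMP``  -- always proposes a commitment, cooperates if accepted, refuses
  to play if declined.
* ``C``     -- unconditional cooperator; accepts commitment proposals.
* ``D``     -- unconditional defector; declines commitment proposals.
* ``FAKE``  -- accepts proposals, then defects (and pays the compensation).
* ``FREE``  -- defects unless proposed a deal, which it accepts and honours.

C, COMP and IRCOM intend to cooperate; D, FAKE and FREE intend to defect --
the intended action is what IRCOM's recognition machinery targets.

Conventions for situations the interaction rules leave open (two proposers
meeting, declined deals, IRCOM meeting IRCOM) are documented in
``docs/methods.md``; briefly: two simultaneous proposers split ``eps``
equally, a declined proposal still costs the sole proposer the full ``eps``,
COMP proposes first (and pays the full cost) when meeting IRCOM, and in
IRCOM-IRCOM encounters each side resolves its own confidence draw
independently, which reproduces the marginal cooperation probability
``theta + p_c``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "STRATEGIES",
    "GameParams",
    "IRParams",
    "ReliancePartition",
    "StrategyTraits",
    "STRATEGY_TRAITS",
    "PayoffMatrix",
    "reliance_partition",
    "pair_payoff",
    "build_payoff_matrix",
]

#: Canonical strategy order for every matrix in the package.
STRATEGIES: tuple[str, ...] = ("IRCOM", "COMP", "C", "D", "FAKE", "FREE")


class ParameterError(ValueError):
    """A model parameter lies outside its admissible domain."""


@dataclass(frozen=True)
class GameParams:
    """Economic parameters of the commitment-augmented Donor game.

    Parameters
    ----------
    b, c
        Benefit and cost of cooperation; require ``b > c > 0`` so that the
        Donor-game payoffs satisfy ``T > R > P > S``.
    eps
        Cost of arranging a commitment deal (>= 0).
    delta
        Compensation owed by a committed defector (>= 0).
    """

    b: float
    c: float
    eps: float = 0.0
    delta: float = 0.0
    _trps: tuple[float, float, float, float] | None = field(
        default=None, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        if self._trps is None:
            if not (self.b > self.c > 0):
                raise ParameterError(
                    f"require b > c > 0, got b={self.b}, c={self.c}"
                )
        else:
            t, r, p, s = self._trps
            if not (t > r > p > s):
                raise ParameterError(
                    f"payoffs must satisfy T > R > P > S, got {self._trps}"
                )
        if self.eps < 0 or self.delta < 0:
            raise ParameterError("eps and delta must be non-negative")

    @classmethod
    def from_trps(
        cls, T: float, R: float, P: float, S: float, eps: float = 0.0, delta: float = 0.0
    ) -> "GameParams":
        """Construct from a general PD payoff quadruple (ordering enforced)."""
        return cls(b=T, c=-S if S < 0 else 1.0, eps=eps, delta=delta, _trps=(T, R, P, S))

    # Donor-game payoffs unless a general quadruple was supplied.
    @property
    def T(self) -> float:
        return self._trps[0] if self._trps else self.b

    @property
    def R(self) -> float:
        return self._trps[1] if self._trps else self.b - self.c

    @property
    def P(self) -> float:
        return self._trps[2] if self._trps else 0.0

    @property
    def S(self) -> float:
        return self._trps[3] if self._trps else -self.c


@dataclass(frozen=True)
class IRParams:
    """Intention-recognition knobs.

    ``theta`` is the confidence threshold in [0, 1] below which IRCOM falls
    back on proposing a commitment; ``r`` is the accuracy-to-confidence ratio
    (prediction accuracy ``y = min(r * x, 1)`` at confidence ``x``).
    """

    theta: float
    r: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.theta <= 1.0):
            raise ParameterError(f"theta must lie in [0, 1], got {self.theta}")
        if not self.r > 0:
            raise ParameterError(f"r must be positive, got {self.r}")


@dataclass(frozen=True)
class ReliancePartition:
    """Probabilities of IRCOM's three modes in a single encounter.

    ``p_commit`` (= theta): the confidence draw falls at or below the
    threshold and IRCOM proposes a commitment.  ``p_c`` / ``p_w``: IRCOM
    relies on its prediction and the prediction is correct / wrong.
    The three components sum to 1.
    """

    p_commit: float
    p_c: float
    p_w: float

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.p_commit, self.p_c, self.p_w)


def reliance_partition(ir: IRParams) -> ReliancePartition:
    """Split IRCOM's behaviour into commit / rely-correct / rely-wrong mass.

    With confidence ``x ~ U(0, 1)`` and accuracy ``y = min(r * x, 1)``:

    * ``p_commit = theta``,
    * ``p_c = integral_theta^1 min(r x, 1) dx`` (piecewise at ``x = 1/r``
      when ``r > 1``),
    * ``p_w = (1 - theta) - p_c``.
    """
    theta, r = ir.theta, ir.r
    if r <= 1.0:
        # accuracy never saturates on [theta, 1]
        p_c = r * (1.0 - theta * theta) / 2.0
    else:
        x_star = 1.0 / r
        if theta >= x_star:
            # accuracy saturated over the whole reliance range
            p_c = 1.0 - theta
        else:
            p_c = r * (x_star * x_star - theta * theta) / 2.0 + (1.0 - x_star)
    p_w = (1.0 - theta) - p_c
    return ReliancePartition(p_commit=theta, p_c=p_c, p_w=p_w)


# ---------------------------------------------------------------------------
# Behavioural trait table (shared with the agent-based simulator)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StrategyTraits:
    """Behavioural flags of one strategy.

    ``proposes``: "always", "never" or "conditional" (IRCOM, when its
    confidence draw is at or below theta).  ``accepts``: whether a received
    proposal is accepted.  ``deal_action`` / ``plain_action``: move inside an
    accepted deal / in a plain game ("C", "D", or "predict" for
    prediction-driven).  ``intends_cooperate``: the intention IRCOM's
    recognition targets.
    """

    proposes: str
    accepts: bool
    deal_action: str
    plain_action: str
    intends_cooperate: bool


STRATEGY_TRAITS: dict[str, StrategyTraits] = {
    "IRCOM": StrategyTraits("conditional", True, "predict", "predict", True),
    "COMP": StrategyTraits("always", True, "C", "C", True),
    "C": StrategyTraits("never", True, "C", "C", True),
    "D": StrategyTraits("never", False, "D", "D", False),
    "FAKE": StrategyTraits("never", True, "D", "D", False),
    "FREE": StrategyTraits("never", True, "C", "D", False),
}


# ---------------------------------------------------------------------------
# Pairwise expected payoffs
# ---------------------------------------------------------------------------


def _pd(g: GameParams, my_coop: bool, other_coop: bool) -> float:
    """One-shot PD payoff to `me` given both actions."""
    if my_coop:
        return g.R if other_coop else g.S
    return g.T if other_coop else g.P


def _ircom_vs_ircom(g: GameParams, part: ReliancePartition) -> float:
    """Expected payoff of IRCOM against IRCOM.

    Each side is independently in mode COMMIT (prob theta, cooperates and
    proposes), RELY-CORRECT (prob p_c, cooperates) or RELY-WRONG (prob p_w,
    defects).  Proposers split eps when both commit; a sole proposer pays it
    in full.  If at least one side proposed, a deal exists and a defecting
    party pays delta to the other.  The marginal cooperation probability is
    exactly theta + p_c.
    """
    modes = (
        ("K", part.p_commit, True),
        ("RC", part.p_c, True),
        ("RW", part.p_w, False),
    )
    total = 0.0
    for a, pa, coop_a in modes:
        for bmode, pb, coop_b in modes:
            w = pa * pb
            if w == 0.0:
                continue
            pay = _pd(g, coop_a, coop_b)
            if a == "K":
                pay -= g.eps / 2.0 if bmode == "K" else g.eps
            if a == "K" or bmode == "K":  # a deal exists
                if not coop_b:
                    pay += g.delta
                if not coop_a:
                    pay -= g.delta
            total += w * pay
    return total


def _pair(row: str, col: str, g: GameParams, ir: IRParams) -> float:
    """Expected payoff of the row strategy against the column strategy."""
    R, S, T, P = g.R, g.S, g.T, g.P
    eps, delta = g.eps, g.delta
    part = reliance_partition(ir)
    th, p_c, p_w = part.as_tuple()

    plain = {"C": True, "D": False, "FAKE": False, "FREE": False}

    if row == "IRCOM" and col == "IRCOM":
        return _ircom_vs_ircom(g, part)

    if row == "COMP":
        if col == "COMP":
            return R - eps / 2.0
        if col == "IRCOM":
            # COMP proposes first and pays the full arrangement cost
            return R - eps
        if col == "D":
            return -eps  # proposal declined, no game played
        if col == "FAKE":
            return S + delta - eps
        # C and FREE accept and cooperate
        return R - eps

    if row == "IRCOM":
        if col == "COMP":
            return R  # COMP proposed first; IRCOM accepts and cooperates
        # commit branch (prob theta) + reliance branches against a
        # non-proposing opponent with a fixed plain-game action
        opp_coop = plain[col]
        opp_intends = STRATEGY_TRAITS[col].intends_cooperate
        if col == "D":
            commit = -eps  # declined
        elif col == "FAKE":
            commit = S + delta - eps
        else:  # C, FREE accept and cooperate
            commit = R - eps
        # correct prediction -> match the opponent's intention
        rely_correct = _pd(g, opp_intends, opp_coop)
        rely_wrong = _pd(g, not opp_intends, opp_coop)
        return th * commit + p_c * rely_correct + p_w * rely_wrong

    if col == "COMP":
        if row == "D":
            return P  # declined the deal, no game
        if row == "FAKE":
            return T - delta
        return R  # C, FREE cooperate inside the deal

    if col == "IRCOM":
        my_coop = plain[row]
        my_intends = STRATEGY_TRAITS[row].intends_cooperate
        if row == "D":
            commit = P  # declines IRCOM's proposal
        elif row == "FAKE":
            commit = T - delta
        else:
            commit = R
        rely_correct = _pd(g, my_coop, my_intends)
        rely_wrong = _pd(g, my_coop, not my_intends)
        return th * commit + p_c * rely_correct + p_w * rely_wrong

    # both in {C, D, FAKE, FREE}: plain one-shot PD, nobody proposes
    return _pd(g, plain[row], plain[col])


def pair_payoff(row: str, col: str, g: GameParams, ir: IRParams) -> float:
    """Expected one-shot payoff of strategy ``row`` against strategy ``col``.

    Raises
    ------
    KeyError
        If either label is not one of the six strategies.
    """
    for label in (row, col):
        if label not in STRATEGIES:
            raise KeyError(f"unknown strategy label {label!r}")
    return _pair(row, col, g, ir)


@dataclass(frozen=True)
class PayoffMatrix:
    """6x6 expected payoff matrix in the canonical strategy order."""

    values: np.ndarray
    labels: tuple[str, ...] = STRATEGIES

    def __post_init__(self) -> None:
        a = np.asarray(self.values, dtype=float)
        q = len(self.labels)
        if a.shape != (q, q):
            raise ValueError(f"expected a {q}x{q} matrix, got shape {a.shape}")
        if not np.all(np.isfinite(a)):
            raise ValueError("payoff matrix contains non-finite entries")
        object.__setattr__(self, "values", a)

    def __getitem__(self, pair: tuple[str, str]) -> float:
        row, col = pair
        return float(self.values[self.labels.index(row), self.labels.index(col)])

    def restrict(self, labels: Iterable[str]) -> "PayoffMatrix":
        """Sub-matrix over a subset of strategies (canonical order preserved)."""
        keep = tuple(s for s in self.labels if s in set(labels))
        idx = [self.labels.index(s) for s in keep]
        return PayoffMatrix(self.values[np.ix_(idx, idx)], keep)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.labels), columns=list(self.labels))

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"labels": list(self.labels), "values": self.values.tolist()},
                fh,
                indent=2,
            )


def build_payoff_matrix(g: GameParams, ir: IRParams) -> PayoffMatrix:
    """Assemble the full 6x6 expected payoff matrix from :func:`pair_payoff`."""
    q = len(STRATEGIES)
    m = np.empty((q, q))
    for i, row in enumerate(STRATEGIES):
        for j, col in enumerate(STRATEGIES):
            m[i, j] = _pair(row, col, g, ir)
    return PayoffMatrix(m)
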