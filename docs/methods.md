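# Methods

## The game and the interaction conventions

The stage game is the Donor game, a Prisoner's Dilemma with T = b, R = b − c,
P = 0, S = −c and b > c > 0 (a general T > R > P > S quadruple is accepted
through `GameParams.from_trps`). A commitment stage may precede it: a
proposer pays an arrangement cost ε; an accepted deal binds both players,
and a committed player who defects pays the compensation δ to the
co-player.

The pairwise interaction rules for the six strategies leave a few
situations open that the closed-form payoff table must fix. The conventions
adopted here, applied consistently in both the analytic table
(`ircom.payoffs`) and the event-level Monte-Carlo sampler (`ircom.abm`):

* **Declined deals.** Only D declines proposals. A declined deal means no
  game is played; the proposer has already sunk the full ε.
* **Two proposers.** When both players propose (COMP–COMP, or two IRCOMs
  both below threshold) they split the cost, ε/2 each.
* **COMP meets IRCOM.** COMP proposes first — it pays the full ε while
  IRCOM spends its time deliberating — and IRCOM accepts and cooperates,
  earning R. At θ = 1 this makes IRCOM a strictly better unconditional
  proposer, which matters for the interpretation of baseline comparisons
  (below).
* **Intended actions.** C, COMP and IRCOM intend to cooperate; D, FAKE and
  FREE intend to defect. A correct prediction makes IRCOM match the
  co-player's intention; a wrong one makes it do the opposite.
* **Accuracy clamp.** Prediction accuracy is y = min(r·x, 1): the ratio r
  is meaningful up to ~4, and a probability cannot exceed 1. The reliance
  integrals are therefore piecewise at x = 1/r when r > 1:
  p_c = r(1 − θ²)/2 for r ≤ 1, and 1 − 1/(2r) − rθ²/2 (or 1 − θ once
  θ ≥ 1/r) otherwise.
* **IRCOM vs IRCOM.** Each side independently is in mode COMMIT (prob θ),
  RELY-CORRECT (p_c) or RELY-WRONG (p_w = 1 − θ − p_c) and cooperates in the
  first two modes; proposers pay ε as above, and in any encounter with at
  least one proposal a defecting side pays δ. A received proposal does not
  override the receiver's own reliance decision. This is the minimal
  convention that reproduces the marginal cooperation probability θ + p_c,
  which is the one quantitative anchor available for this encounter; the
  expected δ transfers cancel by symmetry.

## Finite-population dynamics

Payoffs in a population with k A-players among N exclude self-interaction:
f_A = ((k−1)π_AA + (N−k)π_AB)/(N−1). Imitation follows the Fermi rule with
strength β; β = 0 is neutral drift. The fixation probability of a single
mutant uses the standard birth–death closed form; the pair-selection
prefactors of the hopping rates cancel in the ratio, leaving only
e^{−βΔf}. Sums of cumulative log-products are evaluated with `logsumexp`,
so large β·N cannot overflow. At β = 0 the code returns exactly 1/N.

In the small-mutation limit the embedded chain over homogeneous states has
off-diagonal entries ρ_ji/(q − 1). Its stationary distribution is the
eigenvector of the transposed chain at the eigenvalue nearest 1 (negative
entries below 1e−9 after normalization are clipped), with a least-squares
null-space solve as fallback when the eigenproblem degenerates. The two
routes agree to better than 1e−8 on well-posed inputs, and the result is
always validated as a fixed point.

The stronger-than-neutral transition graph contains an edge from resident i
to invader j iff ρ_ji > 1/N, weighted in multiples of the neutral
probability ρ_N = 1/N.

## Agent-based simulator

The simulator realizes the process the analytic machinery summarizes:
asynchronous updates, each picking a focal agent uniformly; with
probability μ the agent explores (uniform random strategy, possibly its
own), otherwise it imitates a random distinct model agent with the Fermi
probability. Payoffs against the current composition are computed exactly
from the payoff matrix (self-excluded) rather than by sampling games — the
expectation is identical and the variance far lower. While the population
is homogeneous, imitation cannot change the state and every event mutates
with probability μ independently, so the simulation jumps a geometric
number of events to the next mutation; this acceleration is exact in
distribution. Runs are reproducible from the seed; time averages weight
every post-update event after a burn-in (default 10% of events) equally.

The event-level interaction sampler (`sample_interactions`) draws IRCOM's
confidence and prediction explicitly and settles proposals, acceptances,
moves and payments case by case. It shares only the trait table with the
closed-form payoffs, so agreement between the two (tested for all 36
ordered pairs) is a genuine cross-check of the algebra.

What the simulator does not emulate: structured populations, synchronous
updating, noisy action implementation, or payoff sampling noise. Agreement
between simulator and analytic stationary distribution therefore validates
the small-mutation reduction and the payoff table, not the behaviour of
the model under network structure or implementation errors.

## Metrics and experiments

* **Cooperation index** (default): Σ_s σ_s·c_s with c_s the probability an
  individual cooperates in a homogeneous s-population — 1 for C and COMP,
  θ + p_c for IRCOM, 0 for D, FAKE and FREE (no deals arise among them).
  A strategy-frequency variant (σ_IRCOM + σ_COMP) is available behind
  `kind="strategy"`.
* **Improvement over baseline**: cooperation index of the six-strategy
  model minus that of the five-strategy model without IRCOM (chain rebuilt
  with q = 5). Removing a strategy changes the uniform mutation kernel
  (q − 1 divisor), so the comparison is not strictly nested; the exact
  consequence is pinned down by a lumpability test: duplicating COMP's
  payoffs onto IRCOM reproduces the five-strategy chain exactly once the
  duplicated phenotype receives twice the mutation weight. Because IRCOM at
  θ = 1 is a strictly better proposer than COMP (see the COMP–IRCOM
  convention), the improvement does not vanish at θ = 1.
* **Optimal threshold θ\***: smallest grid value (default grid 0…1, step
  0.01) maximizing IRCOM's stationary frequency. Near-flat plateaus occur
  at high ε where IRCOM's abundance is low; θ* is then stable only to a
  couple of grid steps.
* Default sweep grids: θ 0–1 step 0.01; ε 0–2 step 0.05; δ 0–6 step 0.25.

## Parameters and defaults

| parameter | meaning | default |
|---|---|---|
| b, c | benefit / cost of cooperation | 4, 1 |
| ε | cost of arranging a deal | **no default; must be supplied** |
| δ | compensation for breaking a deal | 4 |
| θ | confidence threshold | 0.5 (CLI); swept in experiments |
| r | accuracy-to-confidence ratio | 1 |
| N | population size | 100 |
| β | imitation strength | 0.1 |
| μ | exploration rate (simulator) | 1e−3 |

ε deliberately has no default: its canonical value is not part of the
model's standard parameterization, and the interesting regimes range from
cheap (ε ≲ 0.5, unconditional proposing viable) through costly
(ε ≈ 1.5–2, proposers displaced by free-riders while the conditional
recognizer endures — at these ε the recognizer's optimal threshold sits
near 0.28) to prohibitive (ε ≥ b − c, where deals cannot pay for
themselves and free-riders dominate unless prediction accuracy is high).
Qualitative-shape tests scan ε across these regimes rather than assuming a
single value.

## Problem sizes used in tests and the acceptance script

The payoff Monte-Carlo cross-checks use 10⁶ draws per ordered pair (3
standard errors). The simulator-vs-analytic comparison runs 6×10⁷ update
events at μ = 1e−3, N = 100 — thousands of transitions between homogeneous
states, giving per-strategy agreement within 0.05. The brute-force
birth–death oracle for fixation probabilities is solved in 50-digit
arithmetic because the absorption system's conditioning grows like
e^{βΣ|Δf|}.

## Known limitations

* One-shot interactions only; no history-based or repeated-game intention
  recognition, and no implementation noise.
* Well-mixed populations; no structure, groups or networks.
* The small-mutation stationary distribution is exact only as μ → 0; at
  finite μ the simulator spends a small fraction of time in mixed states.
* The confidence distribution is fixed at U(0, 1); only its accuracy
  coupling r is tunable.
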