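"""Parameter sweeps and derived cooperation metrics.

Drives the analytic pipeline (payoff matrix -> fixation matrix ->
small-mutation stationary distribution) over grids of the confidence
threshold theta, the commitment economics (eps, delta) and the
accuracy-to-confidence ratio r, and derives:

* the population-level cooperation index,
* the improvement over the baseline model without the intention-recognition
  strategy (five strategies: COMP, C, D, FAKE, FREE),
* the optimal confidence threshold theta* maximizing IRCOM's abundance.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .dynamics import (
    EvoParams,
    fixation_matrix,
    small_mutation_transition_matrix,
    stationary_distribution,
)
from .payoffs import (
    STRATEGIES,
    GameParams,
    IRParams,
    build_payoff_matrix,
    reliance_partition,
)

__all__ = [
    "SweepSpec",
    "cooperation_index",
    "stationary_for",
    "improvement_over_baseline",
    "optimal_theta",
    "run_sweep",
    "render_figures",
]

logger = logging.getLogger("ircom")

BASELINE_STRATEGIES: tuple[str, ...] = ("COMP", "C", "D", "FAKE", "FREE")

#: Default theta grid for optimal-threshold searches.
DEFAULT_THETA_GRID: np.ndarray = np.round(np.arange(0.0, 1.0 + 1e-9, 0.01), 10)


def stationary_for(
    g: GameParams,
    ir: IRParams,
    evo: EvoParams,
    strategies: Sequence[str] = STRATEGIES,
) -> np.ndarray:
    """Small-mutation stationary distribution over homogeneous states."""
    payoffs = build_payoff_matrix(g, ir).restrict(strategies)
    rho = fixation_matrix(payoffs, evo)
    M = small_mutation_transition_matrix(rho)
    return stationary_distribution(M)


def cooperation_index(
    sigma: np.ndarray,
    g: GameParams,
    ir: IRParams,
    strategies: Sequence[str] = STRATEGIES,
    kind: str = "action",
) -> float:
    """Population cooperation level under stationary distribution ``sigma``.

    ``kind="action"`` (default): stationary-weighted probability that an
    individual cooperates in the homogeneous population of its strategy --
    1 for C and COMP (deals among proposers always form), ``theta + p_c``
    for the intention recognizer, and 0 for D, FAKE and FREE (no proposals
    arise among them, so everyone defects).

    ``kind="strategy"``: combined abundance of the commitment-proposing
    strategies (IRCOM + COMP).
    """
    strategies = tuple(strategies)
    sigma = np.asarray(sigma, dtype=float)
    if kind == "strategy":
        return float(
            sum(s_i for lab, s_i in zip(strategies, sigma) if lab in ("IRCOM", "COMP"))
        )
    if kind != "action":
        raise ValueError(f"unknown cooperation index kind {kind!r}")
    part = reliance_partition(ir)
    per_strategy = {
        "IRCOM": part.p_commit + part.p_c,
        "COMP": 1.0,
        "C": 1.0,
        "D": 0.0,
        "FAKE": 0.0,
        "FREE": 0.0,
    }
    return float(sum(sigma_i * per_strategy[lab] for lab, sigma_i in zip(strategies, sigma)))


def optimal_theta(
    g: GameParams,
    evo: EvoParams,
    r: float,
    grid: Sequence[float] | None = None,
) -> float:
    """Smallest theta on the grid maximizing IRCOM's stationary frequency."""
    grid = DEFAULT_THETA_GRID if grid is None else np.asarray(list(grid), dtype=float)
    if grid.size == 0:
        raise ValueError("theta grid must be non-empty")
    ircom = STRATEGIES.index("IRCOM")
    best_theta, best_freq = None, -np.inf
    for theta in grid:
        sigma = stationary_for(g, IRParams(theta=float(theta), r=r), evo)
        if sigma[ircom] > best_freq + 1e-12:  # strict improvement; ties keep smaller theta
            best_freq = sigma[ircom]
            best_theta = float(theta)
    return best_theta


def improvement_over_baseline(
    g: GameParams,
    ir: IRParams,
    evo: EvoParams,
    kind: str = "action",
) -> float:
    """Cooperation gain from adding the intention recognizer.

    Difference between the cooperation index of the six-strategy model and
    that of the five-strategy baseline without IRCOM (transition chain
    rebuilt with q = 5; the baseline has no theta).
    """
    sigma6 = stationary_for(g, ir, evo)
    coop6 = cooperation_index(sigma6, g, ir, STRATEGIES, kind=kind)
    sigma5 = stationary_for(g, ir, evo, BASELINE_STRATEGIES)
    coop5 = cooperation_index(sigma5, g, ir, BASELINE_STRATEGIES, kind=kind)
    return coop6 - coop5


# ---------------------------------------------------------------------------
# Grid sweeps
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SweepSpec:
    """A grid evaluation of the analytic pipeline.

    ``axes`` maps parameter names (``theta``, ``r``, ``eps``, ``delta``,
    ``b``, ``c``, ``N``, ``beta``) to grids; the Cartesian product is
    evaluated.  ``metrics`` may include ``"cooperation"``, ``"improvement"``
    and ``"optimal_theta"`` (the latter re-optimizes theta at each point and
    ignores a swept theta axis).
    """

    game: GameParams
    ir: IRParams
    evo: EvoParams = EvoParams()
    axes: dict[str, Sequence[float]] = field(default_factory=dict)
    metrics: tuple[str, ...] = ("cooperation",)

    _GAME_FIELDS = ("b", "c", "eps", "delta")
    _IR_FIELDS = ("theta", "r")
    _EVO_FIELDS = ("N", "beta")

    def __post_init__(self) -> None:
        valid = self._GAME_FIELDS + self._IR_FIELDS + self._EVO_FIELDS
        for name, grid in self.axes.items():
            if name not in valid:
                raise ValueError(f"unknown sweep axis {name!r}")
            if len(list(grid)) == 0:
                raise ValueError(f"empty grid for axis {name!r}")

    def point(self, **values) -> tuple[GameParams, IRParams, EvoParams]:
        g = replace(self.game, **{k: v for k, v in values.items() if k in self._GAME_FIELDS})
        ir = replace(self.ir, **{k: v for k, v in values.items() if k in self._IR_FIELDS})
        ev = replace(
            self.evo,
            **{k: (int(v) if k == "N" else v) for k, v in values.items() if k in self._EVO_FIELDS},
        )
        return g, ir, ev


def run_sweep(spec: SweepSpec) -> pd.DataFrame:
    """Evaluate the analytic pipeline at every grid point of ``spec``.

    Returns a tidy long-format frame with one row per grid point: the swept
    parameter values, the six stationary frequencies, and the requested
    metrics.  Infeasible points are recorded with an ``error`` column
    instead of raising.
    """
    names = list(spec.axes)
    grids = [list(spec.axes[n]) for n in names]
    records = []
    for combo in itertools.product(*grids) if names else [()]:
        values = dict(zip(names, combo))
        rec = dict(values)
        try:
            g, ir, evo = spec.point(**values)
            if "optimal_theta" in spec.metrics:
                theta_star = optimal_theta(g, evo, ir.r)
                ir = replace(ir, theta=theta_star)
                rec["optimal_theta"] = theta_star
            sigma = stationary_for(g, ir, evo)
            for lab, s_i in zip(STRATEGIES, sigma):
                rec[f"freq_{lab}"] = s_i
            if "cooperation" in spec.metrics:
                rec["cooperation"] = cooperation_index(sigma, g, ir)
            if "improvement" in spec.metrics:
                rec["improvement"] = improvement_over_baseline(g, ir, evo)
            rec["error"] = ""
        except (ValueError, KeyError) as exc:
            rec["error"] = str(exc)
        logger.info("sweep point %s -> %s", values, rec.get("error") or "ok")
        records.append(rec)
    return pd.DataFrame.from_records(records)


# ---------------------------------------------------------------------------
# Figures
# ---------------------------------------------------------------------------


def render_figures(result: pd.DataFrame, kind: str, path, **kwargs) -> None:
    """Render a sweep result to an image file.

    ``kind="curve"``: strategy frequencies against the single swept axis.
    ``kind="heatmap"``: a metric (default ``cooperation``) over two axes.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    freq_cols = [c for c in result.columns if c.startswith("freq_")]
    axes_cols = [
        c for c in result.columns if c not in freq_cols and c not in
        ("cooperation", "improvement", "optimal_theta", "error")
    ]
    if kind == "curve":
        if len(axes_cols) != 1:
            raise ValueError("curve figures need exactly one swept axis")
        x = axes_cols[0]
        fig, ax = plt.subplots(figsize=(6, 4))
        for c in freq_cols:
            ax.plot(result[x], result[c], label=c.removeprefix("freq_"))
        ax.set_xlabel(x)
        ax.set_ylabel("stationary frequency")
        ax.legend(fontsize=8)
    elif kind == "heatmap":
        if len(axes_cols) != 2:
            raise ValueError("heatmap figures need exactly two swept axes")
        metric = kwargs.get("metric", "cooperation")
        pivot = result.pivot(index=axes_cols[1], columns=axes_cols[0], values=metric)
        fig, ax = plt.subplots(figsize=(6, 4.5))
        im = ax.pcolormesh(pivot.columns, pivot.index, pivot.values, shading="nearest")
        fig.colorbar(im, ax=ax, label=metric)
        ax.set_xlabel(axes_cols[0])
        ax.set_ylabel(axes_cols[1])
    else:
        raise ValueError(f"unknown figure kind {kind!r}")
    stamp = ", ".join(f"{k}={v}" for k, v in kwargs.get("params", {}).items())
    if stamp:
        ax.set_title(stamp, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
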