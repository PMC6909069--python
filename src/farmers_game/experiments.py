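"""Monte Carlo replication, survival summaries, wealth histograms, and the
wealth-equilibrium turn-cost search.

Societies in this model are interesting near *equilibrium*: the turn cost at
which a class's total wealth after the run equals its initial total, so the
population neither runs away rich nor collapses.  The equilibrium search
bisects the turn cost against the Monte Carlo mean wealth change of a target
class, using common replicate seeds at every evaluation so the objective is
monotone in the cost.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .engine import Category, SimulationResult, mix_distribution, run_simulation
from .game_core import GameConfig
from .strategies import STRATEGY_NAME


def replicate_seed(base_seed: int, replicate: int) -> int:
    """Deterministic per-replicate seed split from (base_seed, replicate)."""
    return int(np.random.SeedSequence([base_seed, replicate]).generate_state(1)[0])


@dataclass
class CategoryAggregate:
    initial_count_mean: float
    survival_mean: float
    survival_se: float
    final_wealth_mean: float
    final_wealth_se: float
    initial_wealth_mean: float


@dataclass
class MonteCarloAggregate:
    """Means and standard errors across replicates, per category."""

    categories: dict[Category, CategoryAggregate]
    replicates: int
    base_seed: int
    total_initial_pop_mean: float
    total_final_pop_mean: float

    def frame(self) -> pd.DataFrame:
        rows = [
            {"initial_class": k[0], "strategy": k[1], **vars(v)}
            for k, v in sorted(self.categories.items())
        ]
        return pd.DataFrame(rows)


def run_monte_carlo(config: GameConfig, replicates: int) -> MonteCarloAggregate:
    """Run ``replicates`` independent simulations and aggregate.

    Replicate ``r`` reuses ``config`` with seed split from
    ``(config.seed, r)``; class and strategy assignments are redrawn in each.
    Survival fractions average final/initial count per category over the
    replicates in which the category is populated.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    kinds, _ = mix_distribution(config)
    cats: list[Category] = [
        (klass, STRATEGY_NAME[k]) for klass in ("poor", "rich") for k in kinds
    ]
    surv: dict[Category, list[float]] = {c: [] for c in cats}
    fwealth: dict[Category, list[float]] = {c: [] for c in cats}
    iwealth: dict[Category, list[float]] = {c: [] for c in cats}
    icount: dict[Category, list[int]] = {c: [] for c in cats}
    tot_init, tot_final = [], []

    for r in range(replicates):
        res = run_simulation(config.with_(seed=replicate_seed(config.seed, r)))
        tot_init.append(res.initial_population)
        tot_final.append(res.final_population)
        for c in cats:
            d = res.categories[c]
            icount[c].append(d["initial_count"])
            fwealth[c].append(d["final_wealth"])
            iwealth[c].append(d["initial_wealth"])
            if d["initial_count"] > 0:
                surv[c].append(d["final_count"] / d["initial_count"])

    def sem(xs: list[float]) -> float:
        if len(xs) < 2:
            return 0.0
        return float(np.std(xs, ddof=1) / math.sqrt(len(xs)))

    categories = {
        c: CategoryAggregate(
            initial_count_mean=float(np.mean(icount[c])),
            survival_mean=float(np.mean(surv[c])) if surv[c] else float("nan"),
            survival_se=sem(surv[c]),
            final_wealth_mean=float(np.mean(fwealth[c])),
            final_wealth_se=sem(fwealth[c]),
            initial_wealth_mean=float(np.mean(iwealth[c])),
        )
        for c in cats
    }
    return MonteCarloAggregate(
        categories=categories,
        replicates=replicates,
        base_seed=config.seed,
        total_initial_pop_mean=float(np.mean(tot_init)),
        total_final_pop_mean=float(np.mean(tot_final)),
    )


def survival_fraction(
    aggregate: MonteCarloAggregate, klass: str, strategy: str
) -> float:
    """Mean final/initial count for one (class, strategy) category."""
    key = (klass, strategy)
    if key not in aggregate.categories:
        raise KeyError(f"category {key} absent from the strategy mix")
    return aggregate.categories[key].survival_mean


def dieoff_fraction(aggregate: MonteCarloAggregate) -> float:
    """Fraction of the initial population lost to the survival threshold."""
    return 1.0 - aggregate.total_final_pop_mean / aggregate.total_initial_pop_mean


@dataclass
class EquilibriumResult:
    turn_cost: float
    residual: float          # mean wealth change of the target class (tokens)
    bracket: tuple[float, float]
    evaluations: int


def _class_wealth_change(
    config: GameConfig, replicates: int, target_class: str
) -> float:
    agg = run_monte_carlo(config, replicates)
    change = 0.0
    for (klass, _strat), ca in agg.categories.items():
        if target_class == "all" or klass == target_class:
            change += ca.final_wealth_mean - ca.initial_wealth_mean
    return change


def find_equilibrium_turn_cost(
    config: GameConfig,
    target_class: str = "rich",
    replicates: int = 100,
    tolerance: float | None = None,
    bracket: tuple[float, float] = (0.5, 1.6),
    width_floor: float = 0.002,
) -> EquilibriumResult:
    """Bisect the turn cost to the target class's wealth equilibrium.

    ``tolerance`` is the acceptable |mean wealth change| in tokens; the
    default is 0.5% of the class's initial total wealth.  Every evaluation
    reuses the same replicate seeds (common random numbers), which makes the
    mean wealth change effectively monotone decreasing in the turn cost and
    bisection sound despite the Monte Carlo noise.
    """
    if target_class not in ("poor", "rich", "all"):
        raise ValueError(f"unknown target class: {target_class!r}")
    lo, hi = bracket
    if tolerance is None:
        agg0 = run_monte_carlo(config.with_(turn_cost=lo, rounds=0), 1)
        init_wealth = sum(
            ca.initial_wealth_mean
            for (k, _), ca in agg0.categories.items()
            if target_class == "all" or k == target_class
        )
        tolerance = 0.005 * init_wealth

    evals = 0

    def f(cost: float) -> float:
        nonlocal evals
        evals += 1
        return _class_wealth_change(
            config.with_(turn_cost=cost), replicates, target_class
        )

    f_lo, f_hi = f(lo), f(hi)
    if f_lo == 0.0:
        return EquilibriumResult(lo, f_lo, (lo, hi), evals)
    if f_hi == 0.0:
        return EquilibriumResult(hi, f_hi, (lo, hi), evals)
    if (f_lo > 0) == (f_hi > 0):
        raise ValueError(
            f"no sign change in bracket {bracket}: f({lo})={f_lo:.3g}, "
            f"f({hi})={f_hi:.3g}"
        )
    mid, f_mid = lo, f_lo
    while hi - lo > width_floor:
        mid = 0.5 * (lo + hi)
        f_mid = f(mid)
        if abs(f_mid) <= tolerance:
            return EquilibriumResult(mid, f_mid, (lo, hi), evals)
        if (f_mid > 0) == (f_lo > 0):
            lo, f_lo = mid, f_mid
        else:
            hi, f_hi = mid, f_mid
    return EquilibriumResult(0.5 * (lo + hi), f_mid, (lo, hi), evals)


@dataclass
class WealthHistogram:
    edges: np.ndarray
    counts: dict[Category, np.ndarray]

    def frame(self) -> pd.DataFrame:
        rows = []
        for (klass, strat), c in sorted(self.counts.items()):
            for i, n in enumerate(c):
                rows.append(
                    {"initial_class": klass, "strategy": strat,
                     "bin_left": self.edges[i], "bin_right": self.edges[i + 1],
                     "count": int(n)}
                )
        return pd.DataFrame(rows)


def wealth_histogram(
    result: SimulationResult,
    bin_width: float = 1.0,
    wealth_range: tuple[float, float] = (0.0, 50.0),
) -> WealthHistogram:
    """Bin the final wealth of live players per category on a common scale.

    Wealth outside ``wealth_range`` is clipped into the terminal bins so
    counts always sum to the category's live population.
    """
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    lo, hi = wealth_range
    edges = np.arange(lo, hi + bin_width, bin_width)
    counts: dict[Category, np.ndarray] = {}
    for klass, strat, w in result.final_agents:
        key = (klass, strat)
        if key not in counts:
            counts[key] = np.zeros(len(edges) - 1, dtype=int)
        idx = int(np.clip((w - lo) // bin_width, 0, len(edges) - 2))
        counts[key][idx] += 1
    return WealthHistogram(edges=edges, counts=counts)


def survival_sweep(
    config: GameConfig, turn_costs: list[float], replicates: int
) -> pd.DataFrame:
    """Tidy frame of survival mean/SE per category across a turn-cost grid."""
    rows = []
    for cost in turn_costs:
        agg = run_monte_carlo(config.with_(turn_cost=cost), replicates)
        for (klass, strat), ca in agg.categories.items():
            rows.append(
                {"turn_cost": cost, "initial_class": klass, "strategy": strat,
                 "survival_mean": ca.survival_mean,
                 "survival_se": ca.survival_se,
                 "final_wealth_mean": ca.final_wealth_mean}
            )
        rows.append(
            {"turn_cost": cost, "initial_class": "all", "strategy": "all",
             "survival_mean": agg.total_final_pop_mean
             / agg.total_initial_pop_mean,
             "survival_se": float("nan"),
             "final_wealth_mean": float("nan")}
        )
    return pd.DataFrame(rows)
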