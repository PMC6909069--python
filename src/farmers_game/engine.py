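"""Simulation engine: rounds of pairwise play, settlement, and survival.

A *round* plays every edge between two live players exactly once, in sorted
edge order.  For each interaction both players decide simultaneously from
the current state, both observe and remember the opponent's move, and both
receive the gross payoff minus the turn cost.  A player whose wealth drops
to or below zero dies immediately, is removed from the network (neighbours
reconnected), and plays no further interactions; dead players are never
replaced.  Edges created by mid-round reconnection enter play from the next
round.

The random stream is consumed in a fixed order — class assignment, strategy
assignment, then per-interaction forgiveness draws — so a configuration and
seed determine the whole trajectory bit for bit.

Two policy switches exist for the points the rules leave open: death can be
checked per interaction (default) or at end of round, and settlement can be
sequential in-place (default) or simultaneous from a round-start snapshot.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .game_core import GameConfig, validate_config
from .lattice_net import Network, build_lattice
from .strategies import (
    STRATEGY_BY_NAME,
    STRATEGY_NAME,
    AgentState,
    StrategyKind,
    decide_move_code,
)

Category = tuple[str, str]  # (initial_class, strategy name)


@dataclass
class RoundLedger:
    """Per-round accounting used by the conservation checks."""

    interactions: int = 0
    gross_sum: float = 0.0
    cost_sum: float = 0.0
    deaths: list[int] = field(default_factory=list)


@dataclass
class Population:
    agents: list[AgentState]
    network: Network
    config: GameConfig
    rng: np.random.Generator
    death_check: str = "interaction"   # "interaction" | "round"
    settlement: str = "sequential"     # "sequential" | "simultaneous"
    reconnect: str = "pairing"         # "pairing" | "clique" | "none"

    def alive_agents(self) -> list[AgentState]:
        return [a for a in self.agents if a.alive]


@dataclass
class SimulationResult:
    """Outcome of one run, resolved by (initial class x strategy) category."""

    seed: int
    categories: dict[Category, dict]
    alive_series: dict[Category, list[int]]     # per-round alive counts
    wealth_series: dict[Category, list[float]]  # per-round total live wealth
    death_log: list[tuple[int, int, str, str]]  # (round, id, class, strategy)
    final_agents: list[tuple[str, str, float]]  # (class, strategy, wealth) of live agents

    @property
    def initial_population(self) -> int:
        return sum(c["initial_count"] for c in self.categories.values())

    @property
    def final_population(self) -> int:
        return sum(c["final_count"] for c in self.categories.values())

    def total_final_wealth(self) -> float:
        return sum(c["final_wealth"] for c in self.categories.values())

    def total_initial_wealth(self) -> float:
        return sum(c["initial_wealth"] for c in self.categories.values())

    def summary_frame(self):
        import pandas as pd

        rows = [
            {"initial_class": k[0], "strategy": k[1], **v}
            for k, v in sorted(self.categories.items())
        ]
        return pd.DataFrame(rows)


def mix_distribution(config: GameConfig) -> tuple[list[StrategyKind], np.ndarray]:
    """Normalized strategy distribution in a fixed, documented order."""
    names = [n for n in STRATEGY_BY_NAME if config.strategy_mix.get(n, 0.0) > 0]
    kinds = [STRATEGY_BY_NAME[n] for n in names]
    w = np.array([config.strategy_mix[n] for n in names], dtype=float)
    return kinds, w / w.sum()


def init_population(
    config: GameConfig,
    death_check: str = "interaction",
    settlement: str = "sequential",
    reconnect: str = "pairing",
) -> Population:
    """Build the lattice and assign classes, wealth, and strategies.

    Each node is independently poor with probability ``density_poor`` (wealth
    ``wealth_poor``) and rich otherwise (``wealth_rich``); its strategy is an
    independent draw from the normalized strategy mix.
    """
    validate_config(config)
    network = build_lattice(config.rows, config.cols, borderless=config.borderless)
    n = network.n_nodes
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    is_poor = rng.random(n) < config.density_poor
    kinds, probs = mix_distribution(config)
    strat_idx = rng.choice(len(kinds), size=n, p=probs)
    agents = [
        AgentState(
            id=i,
            strategy=kinds[strat_idx[i]],
            initial_class="poor" if is_poor[i] else "rich",
            wealth=config.wealth_poor if is_poor[i] else config.wealth_rich,
        )
        for i in range(n)
    ]
    return Population(agents, network, config, rng,
                      death_check=death_check, settlement=settlement,
                      reconnect=reconnect)


def run_round(population: Population, round_index: int = 0) -> RoundLedger:
    """Play every live edge once; return the round's accounting ledger."""
    cfg = population.config
    agents = population.agents
    network = population.network
    rng = population.rng
    payoffs = cfg.payoffs
    r_cc, t_dc = payoffs.reward_cc, payoffs.temptation_dc
    s_cd, p_dd = payoffs.sucker_cd, payoffs.punish_dd
    cost = cfg.turn_cost
    sub_t, mid_t = cfg.subsist_threshold, cfg.middle_threshold
    ratio, forg = cfg.wealth_ratio_trigger, cfg.forgiveness
    per_interaction_death = population.death_check == "interaction"
    sequential = population.settlement == "sequential"
    ledger = RoundLedger()

    edges = network.edges()  # snapshot; reconnection edges play next round
    snapshot_wealth = None if sequential else [a.wealth for a in agents]
    pending: dict[int, float] = {}

    for ia, ib in edges:
        a = agents[ia]
        b = agents[ib]
        if not (a.alive and b.alive):
            continue
        wa = a.wealth if sequential else snapshot_wealth[ia]
        wb = b.wealth if sequential else snapshot_wealth[ib]
        ma = decide_move_code(a.strategy, wa, wb, a.memory.get(ib),
                              sub_t, mid_t, ratio, forg, rng)
        mb = decide_move_code(b.strategy, wb, wa, b.memory.get(ia),
                              sub_t, mid_t, ratio, forg, rng)
        a.memory[ib] = mb
        b.memory[ia] = ma
        if ma:
            gross_a, gross_b = (p_dd, p_dd) if mb else (t_dc, s_cd)
        else:
            gross_a, gross_b = (s_cd, t_dc) if mb else (r_cc, r_cc)
        ledger.interactions += 1
        ledger.gross_sum += gross_a + gross_b
        ledger.cost_sum += 2.0 * cost
        if sequential:
            # net first, as in pair_payoff: cost-neutral payoffs stay exact
            a.wealth = wa + (gross_a - cost)
            b.wealth = wb + (gross_b - cost)
            if per_interaction_death:
                if a.wealth <= 0.0:
                    _kill(population, a, ledger)
                if b.wealth <= 0.0:
                    _kill(population, b, ledger)
        else:
            pending[ia] = pending.get(ia, 0.0) + gross_a - cost
            pending[ib] = pending.get(ib, 0.0) + gross_b - cost

    if not sequential:
        for i, delta in pending.items():
            agents[i].wealth += delta
    if not (sequential and per_interaction_death):
        for a in agents:
            if a.alive and a.wealth <= 0.0:
                _kill(population, a, ledger)
    return ledger


def _kill(population: Population, agent: AgentState, ledger: RoundLedger) -> None:
    population.network.remove_node_reconnect(agent.id, policy=population.reconnect)
    agent.alive = False
    ledger.deaths.append(agent.id)


def run_simulation(
    config: GameConfig,
    death_check: str = "interaction",
    settlement: str = "sequential",
    reconnect: str = "pairing",
) -> SimulationResult:
    """Initialize a population from ``config`` and play ``config.rounds``
    rounds, tracking each (initial class x strategy) category."""
    population = init_population(config, death_check, settlement, reconnect)
    kinds, _ = mix_distribution(config)
    cats: list[Category] = [
        (klass, STRATEGY_NAME[k]) for klass in ("poor", "rich") for k in kinds
    ]
    by_agent = {a.id: (a.initial_class, STRATEGY_NAME[a.strategy])
                for a in population.agents}
    categories = {
        c: {"initial_count": 0, "final_count": 0,
            "initial_wealth": 0.0, "final_wealth": 0.0}
        for c in cats
    }
    for a in population.agents:
        categories[by_agent[a.id]]["initial_count"] += 1
        categories[by_agent[a.id]]["initial_wealth"] += a.wealth

    alive_series = {c: [] for c in cats}
    wealth_series = {c: [] for c in cats}
    death_log: list[tuple[int, int, str, str]] = []

    for r in range(config.rounds):
        ledger = run_round(population, r)
        for node in ledger.deaths:
            klass, strat = by_agent[node]
            death_log.append((r, node, klass, strat))
        counts = {c: 0 for c in cats}
        wealth = {c: 0.0 for c in cats}
        for a in population.agents:
            if a.alive:
                c = by_agent[a.id]
                counts[c] += 1
                wealth[c] += a.wealth
        for c in cats:
            alive_series[c].append(counts[c])
            wealth_series[c].append(wealth[c])

    final_agents: list[tuple[str, str, float]] = []
    for a in population.agents:
        if a.alive:
            c = by_agent[a.id]
            categories[c]["final_count"] += 1
            categories[c]["final_wealth"] += a.wealth
            final_agents.append((c[0], c[1], a.wealth))

    return SimulationResult(
        seed=config.seed,
        categories=categories,
        alive_series=alive_series,
        wealth_series=wealth_series,
        death_log=death_log,
        final_agents=final_agents,
    )
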