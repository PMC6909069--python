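"""Heuristic strategies layered on tit-for-tat.

Every strategy uses classic tit-for-tat as its base behaviour — cooperate on
a first encounter, otherwise echo the opponent's last observed move, with a
small *forgiveness* probability of cooperating instead of retaliating — and
adds at most one wealth-sensitive trigger that forces defection:

* ``TitTat``       — no trigger; the pure base strategy.
* ``Subsist``      — defect while own wealth is at or below the one-round
                     survival threshold (default 4 tokens).
* ``Middle``       — defect while own wealth is at or below the two-round
                     threshold (default 8 tokens); a more conservative Subsist.
* ``Exploit``      — defect when at least twice as wealthy as the opponent.
* ``Thief``        — defect when the opponent is at least twice as wealthy.
* ``AlwaysDefect`` — unconditional defection (the non-cooperating society).

Memory is per-neighbour and memory-one: only the opponent's last observed
move is retained.  Forgiveness changes the emitted move, never the stored
memory.  Strategies are fixed for life; there is no imitation or evolution.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

from .game_core import GameConfig, Move


class StrategyKind(enum.IntEnum):
    TIT_TAT = 0
    SUBSIST = 1
    EXPLOIT = 2
    THIEF = 3
    MIDDLE = 4
    ALWAYS_DEFECT = 5


#: Config-facing names, matching the strategy_mix keys.
STRATEGY_BY_NAME = {
    "TitTat": StrategyKind.TIT_TAT,
    "Subsist": StrategyKind.SUBSIST,
    "Exploit": StrategyKind.EXPLOIT,
    "Thief": StrategyKind.THIEF,
    "Middle": StrategyKind.MIDDLE,
    "AlwaysDefect": StrategyKind.ALWAYS_DEFECT,
}
STRATEGY_NAME = {v: k for k, v in STRATEGY_BY_NAME.items()}


@dataclass
class AgentState:
    """One player: fixed strategy and initial class, mutable wealth/memory."""

    id: int
    strategy: StrategyKind
    initial_class: str            # "poor" | "rich"
    wealth: float
    alive: bool = True
    memory: dict[int, Move] = field(default_factory=dict)


def decide_move_code(
    strategy: int,
    own_wealth: float,
    opponent_wealth: float,
    last_opponent_move: int | None,
    subsist_threshold: float,
    middle_threshold: float,
    wealth_ratio_trigger: float,
    forgiveness: float,
    rng: np.random.Generator,
) -> int:
    """Scalar decision core shared by :func:`decide_move` and the engine.

    ``last_opponent_move`` is the remembered move of this opponent (None on a
    first encounter).  Returns 0 (cooperate) or 1 (defect).  The forgiveness
    draw is the only randomness and is consumed only when tit-for-tat would
    retaliate.
    """
    if strategy == StrategyKind.ALWAYS_DEFECT:
        return 1
    if strategy == StrategyKind.SUBSIST:
        if own_wealth <= subsist_threshold:
            return 1
    elif strategy == StrategyKind.MIDDLE:
        if own_wealth <= middle_threshold:
            return 1
    elif strategy == StrategyKind.EXPLOIT:
        if own_wealth >= wealth_ratio_trigger * opponent_wealth:
            return 1
    elif strategy == StrategyKind.THIEF:
        if opponent_wealth >= wealth_ratio_trigger * own_wealth:
            return 1
    # tit-for-tat base: first encounter or remembered cooperation -> cooperate
    if last_opponent_move is None or last_opponent_move == 0:
        return 0
    if forgiveness > 0.0 and rng.random() < forgiveness:
        return 0
    return 1


def decide_move(
    agent: AgentState,
    opponent: AgentState,
    config: GameConfig,
    rng: np.random.Generator,
) -> Move:
    """Choose ``agent``'s move against ``opponent``."""
    if not (agent.alive and opponent.alive):
        raise ValueError("dead participant in decide_move")
    last = agent.memory.get(opponent.id)
    code = decide_move_code(
        agent.strategy,
        agent.wealth,
        opponent.wealth,
        None if last is None else int(last),
        config.subsist_threshold,
        config.middle_threshold,
        config.wealth_ratio_trigger,
        config.forgiveness,
        rng,
    )
    return Move(code)


def record_outcome(agent: AgentState, opponent_id: int, observed: Move) -> AgentState:
    """Store the opponent's observed move, replacing any earlier memory."""
    agent.memory[opponent_id] = observed
    return agent
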