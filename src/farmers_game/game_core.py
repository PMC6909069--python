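"""Payoff structure, configuration, and settlement arithmetic of the Farmer's Game.

The Farmer's Game is a Prisoner's Dilemma variant in which two neighbouring
"farmers" may jointly work the land between them.  Mutual defection leaves
each player with the subsistence yield; mutual cooperation adds a surplus
split between them; unilateral defection lets the defector carry off the
whole (or part of the) harvest.  Every interaction additionally costs each
player a fixed consumption amount (the *turn cost* — "the players must
eat"), which is what keeps accumulated wealth near the survival threshold.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace


class Move(enum.IntEnum):
    """A player's move in one pairwise interaction."""

    COOPERATE = 0
    DEFECT = 1


# Strategy names accepted in a strategy mix; semantics live in `strategies`.
STRATEGY_NAMES = ("TitTat", "Subsist", "Exploit", "Thief", "Middle", "AlwaysDefect")


@dataclass(frozen=True)
class PayoffMatrix:
    """Gross (pre-consumption) payoffs of the symmetric two-player game.

    Attributes
    ----------
    reward_cc : float
        Tokens to each player under mutual cooperation.
    temptation_dc : float
        Tokens to a defector whose opponent cooperates.
    sucker_cd : float
        Tokens to a cooperator whose opponent defects.
    punish_dd : float
        Tokens to each player under mutual defection.
    """

    reward_cc: float = 1.1
    temptation_dc: float = 2.2
    sucker_cd: float = 0.0
    punish_dd: float = 1.0

    @property
    def is_conservative(self) -> bool:
        """True iff unilateral defection redistributes rather than destroys
        the cooperative surplus: temptation + sucker == 2 * reward."""
        return math.isclose(
            self.temptation_dc + self.sucker_cd, 2.0 * self.reward_cc, abs_tol=1e-12
        )

    def satisfies_pd_ordering(self) -> bool:
        return (
            self.temptation_dc >= self.reward_cc >= self.punish_dd >= self.sucker_cd
        )

    def gross(self, move_self: Move, move_other: Move) -> float:
        if move_self == Move.COOPERATE:
            return self.reward_cc if move_other == Move.COOPERATE else self.sucker_cd
        return self.temptation_dc if move_other == Move.COOPERATE else self.punish_dd


#: Baseline payoffs: 10% cooperative surplus, full-harvest defection.
BASELINE_PAYOFFS = PayoffMatrix(1.1, 2.2, 0.0, 1.0)


def conservative_payoffs(reward_cc: float, punish_dd: float = 1.0) -> PayoffMatrix:
    """Conservative matrix for a given cooperative reward: the defector takes
    the whole joint harvest (2 * reward) and the victim gets nothing."""
    return PayoffMatrix(reward_cc, 2.0 * reward_cc, 0.0, punish_dd)


def _default_mix() -> dict[str, float]:
    return {"TitTat": 1.0, "Subsist": 1.0, "Exploit": 1.0, "Thief": 1.0, "Middle": 1.0}


@dataclass(frozen=True)
class GameConfig:
    """Full configuration of one simulation run.

    Defaults reproduce the baseline study conditions: a 20x20 bordered
    lattice, 50 rounds, turn cost 1.07, poor/wealthy initial wealth 4/10
    split 50-50, tit-for-tat forgiveness 10%, equal-weight five-strategy mix.
    """

    payoffs: PayoffMatrix = BASELINE_PAYOFFS
    turn_cost: float = 1.07       # tokens consumed per player per interaction
    forgiveness: float = 0.10     # P(cooperate) when tit-for-tat would retaliate
    rows: int = 20
    cols: int = 20
    rounds: int = 50
    density_poor: float = 0.5     # P(a node starts poor)
    wealth_poor: float = 4.0
    wealth_rich: float = 10.0
    subsist_threshold: float = 4.0   # Subsist defects at or below this wealth
    middle_threshold: float = 8.0    # Middle defects at or below this wealth
    wealth_ratio_trigger: float = 2.0  # Exploit/Thief defect at this wealth ratio
    strategy_mix: dict[str, float] = field(default_factory=_default_mix)
    borderless: bool = False      # toroidal lattice (scaling-check variant)
    seed: int = 0

    def with_(self, **overrides) -> "GameConfig":
        """Copy with fields replaced (validation is the caller's job)."""
        return replace(self, **overrides)


class ConfigError(ValueError):
    """Raised when a GameConfig violates its invariants; carries the full
    list of violations in ``.violations``."""

    def __init__(self, violations: list[str]):
        self.violations = list(violations)
        super().__init__("; ".join(violations))


def config_violations(config: GameConfig) -> list[str]:
    """Return the list of invariant violations (empty if the config is valid)."""
    v: list[str] = []
    p = config.payoffs
    if not p.satisfies_pd_ordering():
        v.append(
            "PD ordering violated: require temptation_dc >= reward_cc >= "
            f"punish_dd >= sucker_cd, got ({p.reward_cc}, {p.temptation_dc}, "
            f"{p.sucker_cd}, {p.punish_dd})"
        )
    for name in ("forgiveness", "density_poor"):
        x = getattr(config, name)
        if not 0.0 <= x <= 1.0:
            v.append(f"probability out of range: {name}={x}")
    for name in ("rows", "cols", "rounds"):
        x = getattr(config, name)
        if not (isinstance(x, int) and x >= 1) and name != "rounds":
            v.append(f"nonpositive dimension: {name}={x}")
        elif name == "rounds" and (not isinstance(x, int) or x < 0):
            v.append(f"negative round count: rounds={x}")
    if config.turn_cost < 0:
        v.append(f"negative turn cost: {config.turn_cost}")
    for name in ("subsist_threshold", "middle_threshold", "wealth_poor", "wealth_rich"):
        if getattr(config, name) < 0:
            v.append(f"negative threshold or wealth: {name}={getattr(config, name)}")
    if config.wealth_ratio_trigger <= 0:
        v.append(f"nonpositive wealth ratio trigger: {config.wealth_ratio_trigger}")
    mix = config.strategy_mix
    unknown = sorted(set(mix) - set(STRATEGY_NAMES))
    if unknown:
        v.append(f"unknown strategy in mix: {unknown}")
    if any(w < 0 for w in mix.values()):
        v.append("negative strategy weight")
    if sum(mix.values()) <= 0:
        v.append("strategy weights sum to zero")
    return v


def validate_config(config: GameConfig) -> GameConfig:
    """Return ``config`` unchanged if valid, else raise :class:`ConfigError`
    naming every violation."""
    v = config_violations(config)
    if v:
        raise ConfigError(v)
    return config


def pair_payoff(
    move_a: Move,
    move_b: Move,
    payoffs: PayoffMatrix,
    turn_cost: float,
) -> tuple[float, float, float, float]:
    """Settle one interaction.

    Returns ``(gross_a, gross_b, net_a, net_b)`` where gross values come from
    the payoff matrix and net subtracts the per-player consumption cost.
    Amounts are real tokens; no rounding occurs anywhere in settlement.
    """
    gross_a = payoffs.gross(move_a, move_b)
    gross_b = payoffs.gross(move_b, move_a)
    return gross_a, gross_b, gross_a - turn_cost, gross_b - turn_cost
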