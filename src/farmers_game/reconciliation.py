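"""Wealth-relative temptation and cross-country cooperation reconciliation.

The temptation parameter of the Prisoner's Dilemma, b = D|C / C|C, measures
how much more a unilateral defector earns than a mutual cooperator.  Two
wealth-relative variants are implemented:

* for simulated players, b* = D|C / (C|C * w), where w is the player's
  initial wealth divided by 10 — the same payoff looks bigger to a poor
  player;
* for live public-goods participants, the stake at risk is normalized by a
  day's wages in the participant's country (per-capita GDP divided by 250
  work days, or 365 calendar days), giving b = 1 + stake / daily_wage, with
  b = 1 the no-temptation limit.

A temptation -> cooperator-density curve (from published network
simulations) then converts each country's normalized temptation into a
predicted cooperator density, which is compared with the observed fraction
invested in non-individual accounts via a Pearson correlation and a mean
residual (the displacement constant).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


def wealth_relative_temptation(
    defect_payoff: float, cooperate_payoff: float, w: float
) -> float:
    """b* = D|C / (C|C * w): temptation scaled by the wealth weighting w."""
    if cooperate_payoff <= 0 or w <= 0:
        raise ValueError("cooperate_payoff and w must be positive")
    return defect_payoff / (cooperate_payoff * w)


@dataclass(frozen=True)
class TemptationAssessment:
    """Wealth-relative temptation of one payoff pair for one player class."""

    b: float
    w: float

    def __post_init__(self):
        if self.b <= 0 or self.w <= 0:
            raise ValueError("b and w must be positive")


@dataclass(frozen=True)
class TemptationCurve:
    """A temptation -> cooperator-density mapping, e.g. one of the published
    EMAIL/PGP network curves or a synthetic fixture."""

    name: str
    b: tuple[float, ...]
    density: tuple[float, ...]

    def __post_init__(self):
        b = np.asarray(self.b, dtype=float)
        d = np.asarray(self.density, dtype=float)
        if b.size != d.size:
            raise ValueError("b and density must have equal length")
        if b.size and np.any(np.diff(b) <= 0):
            raise ValueError("b knots must be strictly increasing")
        if d.size and (np.any(d < 0) or np.any(d > 1)):
            raise ValueError("densities must lie in [0, 1]")

    @classmethod
    def from_frame(cls, name: str, frame: pd.DataFrame) -> "TemptationCurve":
        return cls(name, tuple(frame["b"]), tuple(frame["density"]))

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame({"b": self.b, "density": self.density})


def predict_density(curve: TemptationCurve, b: float) -> float:
    """Piecewise-linear interpolation of cooperator density at temptation b.

    Outside the knot range the terminal densities are used (clamped, never
    extrapolated).
    """
    if len(curve.b) < 2:
        raise ValueError("curve needs at least 2 points")
    return float(np.interp(b, curve.b, curve.density))


@dataclass(frozen=True)
class CountryRecord:
    """One country's wealth basis and observed public-goods behaviour."""

    name: str
    wealth_basis: float   # USD per capita per year
    stake: float          # USD at risk in the experiment
    divisor: float = 250  # work days (250) or calendar days (365) per year
    observed_other_investment: float = 0.0  # fraction in [0, 1]

    def __post_init__(self):
        if self.wealth_basis <= 0 or self.stake < 0:
            raise ValueError("wealth_basis must be positive, stake nonnegative")
        if self.divisor <= 0:
            raise ValueError("divisor must be positive")
        if not 0.0 <= self.observed_other_investment <= 1.0:
            raise ValueError("observed fraction must lie in [0, 1]")


def normalized_temptation(record: CountryRecord) -> float:
    """b = 1 + stake / (wealth_basis / divisor).

    The stake is measured in multiples of a day's wages; zero stake gives
    b = 1 (no temptation).
    """
    daily_wage = record.wealth_basis / record.divisor
    return 1.0 + record.stake / daily_wage


@dataclass
class ReconciliationResult:
    curve_name: str
    per_country: pd.DataFrame  # name, b, predicted, observed, residual
    r: float                   # Pearson correlation predicted vs observed
    displacement: float        # mean(observed - predicted)


def correlate(
    curve: TemptationCurve, countries: list[CountryRecord]
) -> ReconciliationResult:
    """Predict cooperator density per country and correlate with observation.

    Returns the Pearson r between predictions and observed other-investment
    fractions plus the displacement constant (mean observed - predicted).
    """
    if len(countries) < 3:
        raise ValueError("need at least 3 countries")
    b = np.array([normalized_temptation(c) for c in countries])
    predicted = np.array([predict_density(curve, x) for x in b])
    observed = np.array([c.observed_other_investment for c in countries])
    if np.ptp(predicted) == 0 or np.ptp(observed) == 0:
        raise ValueError("zero variance in predictions or observations")
    r = float(stats.pearsonr(predicted, observed).statistic)
    residual = observed - predicted
    table = pd.DataFrame(
        {"name": [c.name for c in countries], "b": b,
         "predicted": predicted, "observed": observed, "residual": residual}
    )
    return ReconciliationResult(
        curve_name=curve.name,
        per_country=table,
        r=r,
        displacement=float(residual.mean()),
    )


def load_curve_csv(path, name: str | None = None) -> TemptationCurve:
    """Read a curve CSV with columns ``b, density``."""
    frame = pd.read_csv(path)
    return TemptationCurve.from_frame(name or str(path), frame)


def load_country_csv(path) -> list[CountryRecord]:
    """Read a country CSV with columns
    ``name, wealth_basis_usd, stake_usd, divisor, observed_fraction``."""
    frame = pd.read_csv(path)
    return [
        CountryRecord(
            name=row["name"],
            wealth_basis=float(row["wealth_basis_usd"]),
            stake=float(row["stake_usd"]),
            divisor=float(row["divisor"]),
            observed_other_investment=float(row["observed_fraction"]),
        )
        for _, row in frame.iterrows()
    ]


def workbook_to_tables(path, curve_sheets: list[str], country_sheet: str):
    """Thin import utility: extract curve and country tables from a
    supplementary-style workbook into the CSV schemas above."""
    curves = {
        sheet: pd.read_excel(path, sheet_name=sheet) for sheet in curve_sheets
    }
    countries = pd.read_excel(path, sheet_name=country_sheet)
    return curves, countries
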