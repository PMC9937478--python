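"""Premature-mortality productivity losses via the human-capital approach.

Years of life lost (YLL) follow the Global Burden of Disease convention
YLL = N × L, deaths times residual life expectancy at the age of death.
Years of potential *productive* life lost (YPLL) truncate each death's lost
years to the working-age window — from age 15 to the sex-specific pension
age (60 for women, 65 for men) — and are monetised as

    loss = YPLL × monthly wage × 12 × labour-force participation rate.

No discounting or age-weighting is applied by default; an optional annual
discount rate is available for sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .costs import grid_report, integer_shares
from .strata import Stratum

__all__ = [
    "LaborParams",
    "MortalityRecord",
    "ProductivityResult",
    "yll",
    "working_years_lost",
    "productivity_loss",
    "productivity_result",
    "productivity_report",
]


@dataclass(frozen=True)
class LaborParams:
    """Labour-market parameters for the human-capital valuation.

    The average national wage is monthly (INEC reports income per month);
    ``annualization_factor`` converts it to a yearly value.
    """

    participation_rate: float = 0.62
    monthly_wage: float = 765.0          # USD / month
    pension_age_female: float = 60.0
    pension_age_male: float = 65.0
    working_age_start: float = 15.0
    annualization_factor: float = 12.0
    discount_rate: float = 0.0           # annual; 0 = no discounting

    def __post_init__(self) -> None:
        if not 0.0 <= self.participation_rate <= 1.0:
            raise ValueError(
                f"participation_rate must be in [0, 1], got {self.participation_rate}"
            )
        if self.monthly_wage < 0:
            raise ValueError("monthly_wage must be >= 0")
        for attr in ("pension_age_female", "pension_age_male"):
            if getattr(self, attr) <= self.working_age_start:
                raise ValueError(f"{attr} must exceed working_age_start")

    def pension_age(self, sex: str) -> float:
        return self.pension_age_female if sex == "female" else self.pension_age_male


@dataclass(frozen=True)
class MortalityRecord:
    """CVD deaths in one stratum (total, or already attributable, depending
    on the pipeline's mortality mode): count N, residual life expectancy L
    (years) and age at death (band midpoint unless exact ages are known)."""

    outcome: str
    stratum: Stratum
    n_deaths: float
    residual_life_expectancy: float
    age_at_death: float

    def __post_init__(self) -> None:
        if self.n_deaths < 0:
            raise ValueError("n_deaths must be >= 0")
        if self.residual_life_expectancy < 0:
            raise ValueError("residual_life_expectancy must be >= 0")


@dataclass(frozen=True)
class ProductivityResult:
    outcome: str
    stratum: Stratum
    yll: float
    ypll: float
    loss: float

    def __post_init__(self) -> None:
        if not (self.yll >= 0 and self.ypll >= 0 and self.loss >= 0):
            raise ValueError("yll, ypll and loss must be >= 0")
        if self.ypll > self.yll + 1e-9:
            raise ValueError("ypll cannot exceed yll")


def yll(record: MortalityRecord) -> float:
    """Years of life lost: deaths × residual life expectancy."""
    return record.n_deaths * record.residual_life_expectancy


def working_years_lost(age_at_death: float, sex: str,
                       labor: LaborParams = LaborParams()) -> float:
    """Potential working years lost by one death: pension age minus age at
    death, clamped to the working-age window; zero past pension age."""
    if age_at_death < 0:
        raise ValueError("age_at_death must be >= 0")
    return max(0.0, labor.pension_age(sex) - max(age_at_death, labor.working_age_start))


def productivity_loss(ypll: float, labor: LaborParams = LaborParams()) -> float:
    """Monetised loss: YPLL × annualised wage × participation rate.

    With a nonzero discount rate, each lost year t (0-based) is discounted by
    1/(1+r)^t, applied to the average year (simple mid-stream approximation
    is not used; the full annuity sum is).
    """
    if ypll < 0:
        raise ValueError("ypll must be >= 0")
    annual_value = labor.monthly_wage * labor.annualization_factor * labor.participation_rate
    r = labor.discount_rate
    if r == 0.0:
        return ypll * annual_value
    whole, frac = int(ypll), ypll - int(ypll)
    annuity = sum((1.0 + r) ** -t for t in range(whole))
    annuity += frac * (1.0 + r) ** -whole
    return annuity * annual_value


def productivity_result(record: MortalityRecord,
                        labor: LaborParams = LaborParams()) -> ProductivityResult:
    """YLL, YPLL and monetised loss for one mortality record.

    Per-death working years are capped at the residual life expectancy so
    that YPLL never exceeds YLL.
    """
    y = yll(record)
    per_death = min(
        working_years_lost(record.age_at_death, record.stratum.sex, labor),
        record.residual_life_expectancy,
    )
    ypll_val = record.n_deaths * per_death
    return ProductivityResult(
        outcome=record.outcome,
        stratum=record.stratum,
        yll=y,
        ypll=ypll_val,
        loss=productivity_loss(ypll_val, labor),
    )


def productivity_report(results: list[ProductivityResult]):
    """Outcome × sex loss table with totals and integer-percent shares.

    Returns ``(table, outcome_shares, sex_shares, totals)`` where ``totals``
    maps 'yll', 'ypll' and 'loss' to their grand totals.  Empty input yields
    an empty table and zero totals.
    """
    if not results:
        empty = pd.DataFrame(columns=["Total"])
        zero = pd.Series(dtype=float)
        return empty, zero, zero, {"yll": 0.0, "ypll": 0.0, "loss": 0.0}
    df = pd.DataFrame(
        [(r.outcome, r.stratum.sex, r.yll, r.ypll, r.loss) for r in results],
        columns=["outcome", "sex", "yll", "ypll", "loss"],
    )
    by_cell = df.groupby(["outcome", "sex"], sort=False, as_index=False)[
        ["yll", "ypll", "loss"]
    ].sum()
    table = grid_report(by_cell[["outcome", "sex", "loss"]], "outcome", "sex",
                        value="loss")
    outcome_shares = integer_shares(df.groupby("outcome", sort=False)["loss"].sum())
    sex_shares = integer_shares(df.groupby("sex", sort=False)["loss"].sum())
    totals = {
        "yll": float(df["yll"].sum()),
        "ypll": float(df["ypll"].sum()),
        "loss": float(df["loss"].sum()),
    }
    return table, outcome_shares, sex_shares, totals
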