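"""Attributable direct healthcare costs and their tabulation.

The attributable fraction (PAR, in percent) of each disease × service × sex
cell of the national annual cost table is the cell's attributable cost.  All
arithmetic is carried at full floating precision; scaling to "thousand USD"
and integer-percent shares happens only at rendering, so the ±1 rounding
inconsistencies typical of published tables never propagate into the model.

Medication costs that the payer could not supply (stroke and rheumatic heart
disease) are represented as *absent* cells, not zeros: totals silently
exclude them and the report carries a footnote.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CurrencyRate",
    "AttributableCost",
    "ReportTables",
    "attributable_cost",
    "convert",
    "aggregate",
    "grid_report",
    "round_half_away_from_zero",
    "integer_shares",
]

DISEASES = ("CHD", "stroke", "hypertensive", "RHD")
SERVICES = ("hospitalization", "consultation", "medication")


@dataclass(frozen=True)
class CurrencyRate:
    """Costa Rican colones per US dollar (₡600/USD at end of 2018)."""

    crc_per_usd: float = 600.0

    def __post_init__(self) -> None:
        if not self.crc_per_usd > 0:
            raise ValueError("exchange rate must be > 0")


@dataclass(frozen=True)
class AttributableCost:
    """Attributable annual cost of one disease × service × sex cell, with an
    optional 95% uncertainty interval once Monte Carlo has run."""

    disease: str
    service: str
    sex: str
    point: float
    ui_low: float | None = None
    ui_high: float | None = None

    def __post_init__(self) -> None:
        if self.point < 0:
            raise ValueError("attributable cost must be >= 0")
        if self.ui_low is not None and self.ui_high is not None:
            if not self.ui_low <= self.point <= self.ui_high:
                raise ValueError(
                    f"interval [{self.ui_low}, {self.ui_high}] must bracket point {self.point}"
                )


def attributable_cost(par: float, total_cost: float) -> float:
    """(par / 100) × total_cost."""
    if total_cost < 0:
        raise ValueError("total cost must be >= 0")
    return par / 100.0 * total_cost


def convert(amount_crc: float, rate: CurrencyRate = CurrencyRate()) -> float:
    """Colones → US dollars at the fixed nominal exchange rate."""
    return amount_crc / rate.crc_per_usd


def round_half_away_from_zero(x: float) -> int:
    """Commercial rounding (0.5 → 1, −0.5 → −1), as printed tables use."""
    return int(math.floor(abs(x) + 0.5) * (1 if x >= 0 else -1))


def integer_shares(components: pd.Series) -> pd.Series:
    """Each component as an integer percent of the series total."""
    total = components.sum()
    if total == 0:
        return pd.Series(0, index=components.index, dtype=int)
    return components.apply(lambda v: round_half_away_from_zero(100.0 * v / total))


@dataclass
class ReportTables:
    """Aggregated attributable-cost tables (full precision; render separately)."""

    cells: pd.DataFrame
    disease_by_service: pd.DataFrame
    service_shares: pd.Series
    disease_shares: pd.Series
    sex_tables: dict = field(default_factory=dict)
    sex_shares: dict = field(default_factory=dict)
    grand_total: float = 0.0
    excluded: tuple = ()


def grid_report(cells: pd.DataFrame, row: str, col: str,
                value: str = "point") -> pd.DataFrame:
    """Pivot long cells into a row × col table with 'Total' margins.

    Absent cells stay NaN (excluded from sums); duplicate keys are an error.
    """
    if cells.duplicated(subset=[row, col]).any():
        dupes = cells[cells.duplicated(subset=[row, col], keep=False)]
        raise ValueError(f"duplicate cells for the same key:\n{dupes}")
    table = cells.pivot(index=row, columns=col, values=value)
    table["Total"] = table.sum(axis=1, skipna=True)
    table.loc["Total"] = table.sum(axis=0, skipna=True)
    return table


def aggregate(cells: list[AttributableCost]) -> ReportTables:
    """Disease × service totals, per-service sex splits, shares, grand total.

    ``cells`` must form a consistent grid over disease × service × sex with
    no duplicates; unavailable cells are simply not in the list.
    """
    df = pd.DataFrame(
        [(c.disease, c.service, c.sex, c.point, c.ui_low, c.ui_high) for c in cells],
        columns=["disease", "service", "sex", "point", "ui_low", "ui_high"],
    )
    if df.duplicated(subset=["disease", "service", "sex"]).any():
        raise ValueError("duplicate attributable-cost cell for the same disease/service/sex")

    by_ds = (
        df.groupby(["disease", "service"], sort=False)["point"].sum().reset_index()
    )
    disease_by_service = grid_report(by_ds, "disease", "service")
    grand_total = float(df["point"].sum())

    service_totals = df.groupby("service", sort=False)["point"].sum()
    disease_totals = df.groupby("disease", sort=False)["point"].sum()
    service_shares = integer_shares(service_totals)
    disease_shares = integer_shares(disease_totals)

    sex_tables: dict = {}
    sex_shares: dict = {}
    for service, sub in df.groupby("service", sort=False):
        sex_tables[service] = grid_report(
            sub[["disease", "sex", "point"]], "disease", "sex"
        )
        sex_shares[service] = integer_shares(sub.groupby("sex", sort=False)["point"].sum())

    present = {(d, s) for d, s in zip(df["disease"], df["service"])}
    full_grid = {(d, s) for d in df["disease"].unique() for s in df["service"].unique()}
    excluded = tuple(sorted(full_grid - present))

    return ReportTables(
        cells=df,
        disease_by_service=disease_by_service,
        service_shares=service_shares,
        disease_shares=disease_shares,
        sex_tables=sex_tables,
        sex_shares=sex_shares,
        grand_total=grand_total,
        excluded=excluded,
    )


def render_thousands(table: pd.DataFrame) -> pd.DataFrame:
    """Display scaling to 'thousand USD' with half-away-from-zero rounding."""
    return table.apply(
        lambda col: col.map(
            lambda v: round_half_away_from_zero(v / 1000.0) if pd.notna(v) else np.nan
        )
    )
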