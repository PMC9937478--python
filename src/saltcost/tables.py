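"""CSV readers and writers for the model's parameter tables.

Dialect: UTF-8, comma separator, period decimal, mandatory header row.
Currency is stored in raw units (not thousands); scaling to "thousand USD"
is a rendering concern only.  Every reader validates the table's schema and
invariants and raises :class:`TableError` naming the offending field.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml

from .costs import CurrencyRate, DISEASES, SERVICES
from .exposure import IntakeDistribution
from .productivity import LaborParams
from .strata import SEXES, validate_age_bands
from .synthetic_inputs import InputBundle

__all__ = ["TableError", "read_strata", "read_rr_table", "read_cost_table",
           "read_mortality", "save_bundle", "load_bundle"]

STRATA_COLUMNS = ["sex", "age_group", "population"]
RR_COLUMNS = ["outcome", "sex", "age_group", "rr_per_mmHg"]
COST_COLUMNS = ["disease", "service", "sex", "annual_cost", "currency", "available"]
MORTALITY_COLUMNS = ["outcome", "sex", "age_group", "age_at_death", "n_deaths",
                     "residual_life_expectancy"]


class TableError(ValueError):
    """A parameter table violates its schema or an invariant."""


def _require_columns(df: pd.DataFrame, columns, name: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise TableError(f"{name}: missing columns {missing}")


def _check_sex(df: pd.DataFrame, name: str) -> None:
    bad = set(df["sex"]) - set(SEXES)
    if bad:
        raise TableError(f"{name}.sex: unknown values {sorted(bad)}")


def read_strata(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, STRATA_COLUMNS, "strata")
    _check_sex(df, "strata")
    if (df["population"] < 0).any():
        raise TableError("strata.population: negative values")
    for sex, sub in df.groupby("sex"):
        validate_age_bands(list(sub["age_group"]))
    return df[STRATA_COLUMNS]


def read_rr_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, RR_COLUMNS, "rr_table")
    _check_sex(df, "rr_table")
    if (df["rr_per_mmHg"] <= 0).any():
        raise TableError("rr_table.rr_per_mmHg: must be > 0")
    if df.duplicated(subset=["outcome", "sex", "age_group"]).any():
        raise TableError("rr_table: duplicate outcome/sex/age_group record")
    return df[RR_COLUMNS]


def read_cost_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, COST_COLUMNS, "cost_table")
    _check_sex(df, "cost_table")
    df["available"] = df["available"].astype(bool)
    bad_disease = set(df["disease"]) - set(DISEASES)
    if bad_disease:
        raise TableError(f"cost_table.disease: unknown values {sorted(bad_disease)}")
    bad_service = set(df["service"]) - set(SERVICES)
    if bad_service:
        raise TableError(f"cost_table.service: unknown values {sorted(bad_service)}")
    bad_ccy = set(df["currency"]) - {"USD", "CRC"}
    if bad_ccy:
        raise TableError(f"cost_table.currency: unknown values {sorted(bad_ccy)}")
    avail = df[df["available"]]
    if (avail["annual_cost"] < 0).any() or avail["annual_cost"].isna().any():
        raise TableError("cost_table.annual_cost: available cells must be >= 0")
    if df.duplicated(subset=["disease", "service", "sex"]).any():
        raise TableError("cost_table: duplicate disease/service/sex cell")
    return df[COST_COLUMNS]


def read_mortality(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, MORTALITY_COLUMNS, "mortality")
    _check_sex(df, "mortality")
    if (df["n_deaths"] < 0).any():
        raise TableError("mortality.n_deaths: must be >= 0")
    if (df["residual_life_expectancy"] < 0).any():
        raise TableError("mortality.residual_life_expectancy: must be >= 0")
    if (df["age_at_death"] < 0).any():
        raise TableError("mortality.age_at_death: must be >= 0")
    return df[MORTALITY_COLUMNS]


def save_bundle(bundle: InputBundle, directory) -> Path:
    """Write a bundle as four CSVs plus a params.yaml; returns the directory."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    bundle.strata.to_csv(d / "strata.csv", index=False)
    bundle.rr_table.to_csv(d / "rr_table.csv", index=False)
    bundle.cost_table.to_csv(d / "cost_table.csv", index=False)
    bundle.mortality.to_csv(d / "mortality.csv", index=False)
    params = {
        "baseline": {"mean": bundle.baseline.mean, "sd": bundle.baseline.sd,
                     "kcal_anchor": bundle.baseline.kcal_anchor},
        "counterfactual": {"mean": bundle.counterfactual.mean,
                           "sd": bundle.counterfactual.sd,
                           "kcal_anchor": bundle.counterfactual.kcal_anchor},
        "labor": {
            "participation_rate": bundle.labor.participation_rate,
            "monthly_wage": bundle.labor.monthly_wage,
            "pension_age_female": bundle.labor.pension_age_female,
            "pension_age_male": bundle.labor.pension_age_male,
            "working_age_start": bundle.labor.working_age_start,
            "annualization_factor": bundle.labor.annualization_factor,
            "discount_rate": bundle.labor.discount_rate,
        },
        "currency": {"crc_per_usd": bundle.currency.crc_per_usd},
    }
    with open(d / "params.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(params, fh, sort_keys=True)
    return d


def load_bundle(directory) -> InputBundle:
    """Read a bundle back from :func:`save_bundle`'s layout, fully validated."""
    d = Path(directory)
    with open(d / "params.yaml", encoding="utf-8") as fh:
        params = yaml.safe_load(fh)
    return InputBundle(
        strata=read_strata(d / "strata.csv"),
        baseline=IntakeDistribution(**params["baseline"]),
        counterfactual=IntakeDistribution(**params["counterfactual"]),
        rr_table=read_rr_table(d / "rr_table.csv"),
        cost_table=read_cost_table(d / "cost_table.csv"),
        mortality=read_mortality(d / "mortality.csv"),
        labor=LaborParams(**params["labor"]),
        currency=CurrencyRate(**params["currency"]),
    )
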