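from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from saltcost import (CurrencyRate, InputBundle, IntakeDistribution,
                      LaborParams, default_fixture)

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def fixture_bundle() -> InputBundle:
    return default_fixture()


def make_small_bundle(
    *,
    mean: float = 10.0,
    sd: float = 5.4,
    cf_mean: float = 5.0,
    cf_sd: float = 2.65,
    rr_per_mmHg: dict | None = None,
    hosp_cost: float = 1_000_000.0,
) -> InputBundle:
    """A compact 2-outcome × 2-sex × 2-band bundle for fast end-to-end runs.

    ``rr_per_mmHg`` maps (outcome, sex, age_group) to the per-mmHg risk
    ratio; unspecified strata default to 1.02.
    """
    bands = ["45-49", "50-54"]
    sexes = ["male", "female"]
    outcomes = ["CHD", "stroke"]
    rr_per_mmHg = rr_per_mmHg or {}

    strata = pd.DataFrame(
        [(s, b, 100_000.0) for s in sexes for b in bands],
        columns=["sex", "age_group", "population"],
    )
    rr_rows = [
        (o, s, b, rr_per_mmHg.get((o, s, b), 1.02))
        for o in outcomes for s in sexes for b in bands
    ]
    rr_table = pd.DataFrame(rr_rows, columns=["outcome", "sex", "age_group",
                                              "rr_per_mmHg"])
    cost_rows = []
    for o in outcomes:
        for s in sexes:
            cost_rows.append((o, "hospitalization", s, hosp_cost, "USD", True))
            cost_rows.append((o, "consultation", s, hosp_cost / 2, "USD", True))
    cost_table = pd.DataFrame(
        cost_rows,
        columns=["disease", "service", "sex", "annual_cost", "currency", "available"],
    )
    mort_rows = [
        (o, s, b, 47.5 if b == "45-49" else 52.5, 20.0, 30.0)
        for o in outcomes for s in sexes for b in bands
    ]
    mortality = pd.DataFrame(
        mort_rows,
        columns=["outcome", "sex", "age_group", "age_at_death", "n_deaths",
                 "residual_life_expectancy"],
    )
    return InputBundle(
        strata=strata,
        baseline=IntakeDistribution(mean=mean, sd=sd),
        counterfactual=IntakeDistribution(mean=cf_mean, sd=cf_sd),
        rr_table=rr_table,
        cost_table=cost_table,
        mortality=mortality,
        labor=LaborParams(),
        currency=CurrencyRate(),
    )


@pytest.fixture()
def small_bundle() -> InputBundle:
    return make_small_bundle()
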