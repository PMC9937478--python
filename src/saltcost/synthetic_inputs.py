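"""Input bundles: the Costa Rica 2018 fixture and seeded synthetic bundles.

The pipeline consumes an :class:`InputBundle` holding every parameter table
the model needs: population strata, baseline and counterfactual salt-intake
distributions, per-mmHg relative risks by outcome × sex × age group, the
payer's annual cost table by disease × service × sex, attributable-death
mortality records, labour parameters and the currency rate.

:func:`default_fixture` reproduces the published national inputs verbatim
where they are published (intake 10.0±5.4 vs counterfactual 5.0±2.65 g/day,
participation 0.62, wage USD $765/month, pension ages 60/65, ₡600/USD, the
three national cost totals, life expectancy 82.6/77.5).  Tables the payer
and the upstream meta-analyses never published at stratum level — the
disease/sex cost split, the per-mmHg RRs and the death counts — are filled
with clearly synthetic, deterministic defaults so the full pipeline runs
end to end; they are placeholders for user-supplied tables, never estimates
of the unpublished values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .costs import DISEASES, SERVICES, CurrencyRate
from .exposure import IntakeDistribution
from .productivity import LaborParams
from .strata import DEFAULT_AGE_BANDS, SEXES, age_band_midpoint

__all__ = ["InputBundle", "default_fixture", "generate_random_bundle"]

LIFE_EXPECTANCY = {"female": 82.6, "male": 77.5}  # at birth, GBD estimates

# Published national annual cost totals (USD, 2018, nominal)
TOTAL_CONSULTATION_USD = 853_309_618.14
TOTAL_HOSPITALIZATION_USD = 1_584_985_326.39
TOTAL_MEDICATION_USD = 642_090.81  # hypertension + CHD only

# Synthetic splits of the published totals (the payer's stratified appendix
# is not public).  Disease split loosely follows the relative weight of the
# four outcomes in the attributable-cost results; sex split is near-even.
_DISEASE_SPLIT = {"CHD": 0.37, "stroke": 0.25, "hypertensive": 0.28, "RHD": 0.10}
_MEDICATION_SPLIT = {"CHD": 0.10, "hypertensive": 0.90}  # stroke/RHD unavailable
_SEX_SPLIT = {"male": 0.48, "female": 0.52}

# Synthetic per-mmHg RR anchors at the youngest band; log-RR attenuates 10%
# per decade of age (risk ratios flatten in the elderly).
_RR_ANCHORS = {"CHD": 1.028, "stroke": 1.032, "hypertensive": 1.035, "RHD": 1.012}
_RR_DECADE_ATTENUATION = 0.90


@dataclass(frozen=True)
class InputBundle:
    """Everything one model run needs.  Tables are tidy DataFrames:

    - ``strata``: sex, age_group, population
    - ``rr_table``: outcome, sex, age_group, rr_per_mmHg
    - ``cost_table``: disease, service, sex, annual_cost, currency, available
    - ``mortality``: outcome, sex, age_group, age_at_death, n_deaths,
      residual_life_expectancy
    """

    strata: pd.DataFrame
    baseline: IntakeDistribution
    counterfactual: IntakeDistribution
    rr_table: pd.DataFrame
    cost_table: pd.DataFrame
    mortality: pd.DataFrame
    labor: LaborParams
    currency: CurrencyRate

    def with_(self, **kwargs) -> "InputBundle":
        return replace(self, **kwargs)


def _strata_frame(populations) -> pd.DataFrame:
    rows = []
    for sex in SEXES:
        for band in DEFAULT_AGE_BANDS:
            rows.append((sex, band, float(populations[(sex, band)])))
    return pd.DataFrame(rows, columns=["sex", "age_group", "population"])


def _default_populations() -> dict:
    # Smooth synthetic age pyramid, ~3.7M adults total, tapering with age.
    pops = {}
    for sex in SEXES:
        for i, band in enumerate(DEFAULT_AGE_BANDS):
            pops[(sex, band)] = 220_000.0 * math.exp(-0.18 * i) * (1.02 if sex == "female" else 1.0)
    return pops


def _default_rr_table() -> pd.DataFrame:
    rows = []
    for outcome, anchor in _RR_ANCHORS.items():
        for sex in SEXES:
            for band in DEFAULT_AGE_BANDS:
                decades = (age_band_midpoint(band) - age_band_midpoint(DEFAULT_AGE_BANDS[0])) / 10.0
                log_rr = math.log(anchor) * (_RR_DECADE_ATTENUATION ** decades)
                rows.append((outcome, sex, band, math.exp(log_rr)))
    return pd.DataFrame(rows, columns=["outcome", "sex", "age_group", "rr_per_mmHg"])


def _default_cost_table() -> pd.DataFrame:
    rows = []
    service_totals = {
        "hospitalization": TOTAL_HOSPITALIZATION_USD,
        "consultation": TOTAL_CONSULTATION_USD,
        "medication": TOTAL_MEDICATION_USD,
    }
    for service in SERVICES:
        split = _MEDICATION_SPLIT if service == "medication" else _DISEASE_SPLIT
        for disease in DISEASES:
            available = disease in split
            for sex in SEXES:
                cost = (
                    service_totals[service] * split[disease] * _SEX_SPLIT[sex]
                    if available
                    else float("nan")
                )
                rows.append((disease, service, sex, cost, "USD", available))
    return pd.DataFrame(
        rows,
        columns=["disease", "service", "sex", "annual_cost", "currency", "available"],
    )


def _default_mortality() -> pd.DataFrame:
    # Synthetic total CVD deaths by stratum (CHD and stroke only, as in the
    # productivity results): geometric age gradient from age 30, ~4,000
    # deaths in total, roughly the scale of national CVD mortality.
    rows = []
    for outcome, base in (("CHD", 16.0), ("stroke", 11.0)):
        for sex in SEXES:
            for i, band in enumerate(DEFAULT_AGE_BANDS):
                mid = age_band_midpoint(band)
                if mid < 30:
                    continue
                n = base * (1.35 ** (i - 3))
                residual = max(LIFE_EXPECTANCY[sex] - mid, 2.0)
                rows.append((outcome, sex, band, mid, round(n, 3), residual))
    return pd.DataFrame(
        rows,
        columns=["outcome", "sex", "age_group", "age_at_death", "n_deaths",
                 "residual_life_expectancy"],
    )


def default_fixture() -> InputBundle:
    """The deterministic Costa Rica 2018 parameter bundle (pure: two calls
    return identical bundles)."""
    return InputBundle(
        strata=_strata_frame(_default_populations()),
        baseline=IntakeDistribution(mean=10.0, sd=5.4, kcal_anchor=2171.0),
        counterfactual=IntakeDistribution(mean=5.0, sd=2.65, kcal_anchor=2171.0),
        rr_table=_default_rr_table(),
        cost_table=_default_cost_table(),
        mortality=_default_mortality(),
        labor=LaborParams(),
        currency=CurrencyRate(crc_per_usd=600.0),
    )


def generate_random_bundle(seed: int, scale: float = 1.0) -> InputBundle:
    """Seeded random bundle for stress testing.

    Deterministic for a fixed seed.  Generated RRs are always >= 1 and
    weakly decreasing with age within each outcome × sex; costs are positive
    (scaled by ``scale``); death counts follow a Poisson-like age gradient.
    """
    rng = np.random.default_rng(seed)
    fixture = default_fixture()

    mean = float(rng.uniform(8.0, 12.0))
    sd = float(rng.uniform(3.0, 6.0))
    baseline = IntakeDistribution(mean=mean, sd=sd, kcal_anchor=2171.0)

    pops = {
        (sex, band): float(rng.uniform(50_000, 300_000) * scale)
        for sex in SEXES
        for band in DEFAULT_AGE_BANDS
    }

    rr_rows = []
    for outcome in DISEASES:
        for sex in SEXES:
            anchor = rng.uniform(1.01, 1.045)
            atten = rng.uniform(0.82, 0.95)
            for band in DEFAULT_AGE_BANDS:
                decades = (age_band_midpoint(band) - 17.5) / 10.0
                rr_rows.append(
                    (outcome, sex, band, math.exp(math.log(anchor) * atten ** decades))
                )
    rr_table = pd.DataFrame(rr_rows, columns=["outcome", "sex", "age_group", "rr_per_mmHg"])

    cost = fixture.cost_table.copy()
    jitter = rng.lognormal(mean=0.0, sigma=0.3, size=len(cost))
    cost["annual_cost"] = cost["annual_cost"] * jitter * scale

    mort_rows = []
    for outcome in ("CHD", "stroke"):
        for sex in SEXES:
            base = rng.uniform(0.5, 3.0)
            for i, band in enumerate(DEFAULT_AGE_BANDS):
                mid = age_band_midpoint(band)
                if mid < 30:
                    continue
                lam = base * (1.3 ** (i - 3)) * scale
                n = float(rng.poisson(max(lam, 0.0)))
                residual = max(LIFE_EXPECTANCY[sex] - mid, 2.0)
                mort_rows.append((outcome, sex, band, mid, n, residual))
    mortality = pd.DataFrame(
        mort_rows,
        columns=["outcome", "sex", "age_group", "age_at_death", "n_deaths",
                 "residual_life_expectancy"],
    )

    return InputBundle(
        strata=_strata_frame(pops),
        baseline=baseline,
        counterfactual=fixture.counterfactual,
        rr_table=rr_table,
        cost_table=cost,
        mortality=mortality,
        labor=fixture.labor,
        currency=fixture.currency,
    )
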