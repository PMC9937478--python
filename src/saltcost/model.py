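"""The deterministic attributable-burden model, vectorised over draws.

One evaluation chains the full pipeline for every outcome × sex × age-group
stratum:

1. discretise the baseline (and counterfactual) intake distribution into
   exposure-bin prevalences;
2. rescale each stratum's per-mmHg relative risk to per-bin relative risks
   through the salt→SBP dose response;
3. collapse to the binary (P, RR) pair and evaluate
   PAR = 100·P(RR−1)/(P(RR−1)+1);
4. attributable fraction = PAR(baseline) − PAR(counterfactual)
   (or PAR(baseline) alone in pure-threshold mode);
5. pool age-specific fractions to the sex level by population weight and
   apply them to the disease × service × sex cost table;
6. apply each stratum's fraction to its CVD deaths and monetise the lost
   working years (human-capital approach).

Every step broadcasts over a leading "draw" axis so the Monte Carlo engine
can push thousands of sampled inputs through in a single call; a
deterministic run is simply the one-draw case with point inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .costs import AttributableCost, aggregate
from .exposure import BinScheme, DoseResponseSpec, bin_mass_matrix, sbp_shift
from .productivity import ProductivityResult, productivity_report, working_years_lost
from .strata import Stratum
from .synthetic_inputs import InputBundle

__all__ = ["ModelSettings", "ModelOutputs", "compute_model", "run_deterministic",
           "DeterministicResult"]


@dataclass(frozen=True)
class ModelSettings:
    """Structural choices of one model run.

    ``counterfactual_mode``: "distribution" subtracts the counterfactual
    scenario's own (small) excess burden; "threshold" defines the
    counterfactual burden as zero.
    ``mortality_kind``: "total" applies the stratum's attributable fraction
    to the death counts; "attributable" takes the counts as already
    attributable (e.g. produced upstream by a macrosimulation).
    """

    bins: BinScheme = field(default_factory=BinScheme)
    dose: DoseResponseSpec = field(default_factory=DoseResponseSpec)
    counterfactual_mode: str = "distribution"
    mortality_kind: str = "total"

    def __post_init__(self) -> None:
        if self.counterfactual_mode not in ("distribution", "threshold"):
            raise ValueError(f"unknown counterfactual_mode {self.counterfactual_mode!r}")
        if self.mortality_kind not in ("total", "attributable"):
            raise ValueError(f"unknown mortality_kind {self.mortality_kind!r}")


@dataclass
class ModelOutputs:
    """All model quantities as (n_draws,) arrays keyed by name.

    Keys: ``par::<outcome>::<sex>::<age_group>`` (attributable fraction in
    percent per stratum), ``af::<outcome>::<sex>`` (population-pooled),
    ``cell::<disease>::<service>::<sex>`` and the ``direct_*`` /
    ``service::*`` / ``disease::*`` / ``sex::*`` cost totals (USD), and the
    productivity totals (USD and years).
    """

    draws: dict
    n_draws: int

    def scalar(self, name: str) -> float:
        arr = self.draws[name]
        return float(arr[0]) if self.n_draws == 1 else float(np.median(arr))


def _rr_key(row) -> tuple:
    return (row.outcome, row.sex, row.age_group)


def compute_model(
    bundle: InputBundle,
    settings: ModelSettings | None = None,
    *,
    intake_means: np.ndarray | None = None,
    rr_values: np.ndarray | None = None,
    cost_values: np.ndarray | None = None,
) -> ModelOutputs:
    """Evaluate the full model; optionally with per-draw sampled inputs.

    ``intake_means``: (n,) sampled baseline mean intakes (g/day).
    ``rr_values``: (n, n_rr_rows) sampled per-mmHg RRs aligned with
    ``bundle.rr_table`` rows.
    ``cost_values``: (n, n_cost_rows) sampled annual costs aligned with
    ``bundle.cost_table`` rows (unavailable cells ignored).
    Omitted inputs use the bundle's point values.
    """
    settings = settings or ModelSettings()
    bins, dose = settings.bins, settings.dose

    if intake_means is not None:
        means = np.asarray(intake_means, dtype=float)
        n = means.shape[0]
    else:
        n = 1
        if rr_values is not None:
            n = max(n, rr_values.shape[0])
        if cost_values is not None:
            n = max(n, cost_values.shape[0])
        means = np.full(n, bundle.baseline.mean)

    mids = bins.midpoints
    shifts = np.array([sbp_shift(m - bins.reference_value, dose) for m in mids])

    masses = bin_mass_matrix(means, bundle.baseline.sd, bins)          # (n, k)
    P = masses[:, 1:].sum(axis=1)                                      # (n,)
    exposed = masses[:, 1:]

    if settings.counterfactual_mode == "distribution":
        cf_masses = bin_mass_matrix(
            bundle.counterfactual.mean, bundle.counterfactual.sd, bins
        )                                                              # (1, k)
        P_cf = cf_masses[:, 1:].sum(axis=1)
        cf_exposed = cf_masses[:, 1:]
    else:
        cf_masses = None

    rr_df = bundle.rr_table.reset_index(drop=True)
    if rr_values is not None:
        rr_mat = np.asarray(rr_values, dtype=float)
        if rr_mat.shape != (n, len(rr_df)):
            raise ValueError("rr_values must align with rr_table rows")
    else:
        rr_mat = np.broadcast_to(rr_df["rr_per_mmHg"].to_numpy(), (n, len(rr_df)))
    if np.any(rr_mat <= 0):
        raise ValueError("relative risks must be > 0")

    draws: dict = {}
    af_stratum: dict = {}

    def _paf(mass_exposed, p, rbin):
        num = (mass_exposed * rbin).sum(axis=1)
        rr_bar = np.where(p > 0, num / np.where(p > 0, p, 1.0), 1.0)
        excess = p * (rr_bar - 1.0)
        return 100.0 * excess / (excess + 1.0), rr_bar

    for j, row in enumerate(rr_df.itertuples(index=False)):
        rr_j = rr_mat[:, j]                                           # (n,)
        rbin = rr_j[:, None] ** shifts[None, 1:]                      # (n, k-1)
        par_b, rr_bar = _paf(exposed, P, rbin)
        if cf_masses is not None:
            par_c, _ = _paf(cf_exposed, P_cf, rbin)
        else:
            par_c = np.zeros(n)
        attrib = par_b - par_c
        key = _rr_key(row)
        af_stratum[key] = attrib
        draws[f"par::{key[0]}::{key[1]}::{key[2]}"] = attrib
        draws[f"par_baseline::{key[0]}::{key[1]}::{key[2]}"] = par_b
        draws[f"P::{key[0]}::{key[1]}::{key[2]}"] = np.broadcast_to(P, (n,))
        draws[f"RR::{key[0]}::{key[1]}::{key[2]}"] = rr_bar

    # --- population-weighted pooling of age-specific fractions to sex level
    strata = bundle.strata
    pop = {(r.sex, r.age_group): r.population for r in strata.itertuples(index=False)}
    sex_pop = strata.groupby("sex")["population"].sum().to_dict()
    outcomes = rr_df["outcome"].unique()
    sexes = rr_df["sex"].unique()
    af_sex: dict = {}
    for outcome in outcomes:
        for sex in sexes:
            acc = np.zeros(n)
            for (o, s, a), arr in af_stratum.items():
                if o == outcome and s == sex:
                    acc = acc + arr * pop.get((s, a), 0.0)
            af_sex[(outcome, sex)] = acc / sex_pop[sex]
            draws[f"af::{outcome}::{sex}"] = af_sex[(outcome, sex)]

    # --- direct costs
    cost_df = bundle.cost_table.reset_index(drop=True)
    if cost_values is not None:
        cost_mat = np.asarray(cost_values, dtype=float)
        if cost_mat.shape != (n, len(cost_df)):
            raise ValueError("cost_values must align with cost_table rows")
    else:
        cost_mat = np.broadcast_to(cost_df["annual_cost"].to_numpy(), (n, len(cost_df)))

    service_tot: dict = {}
    disease_tot: dict = {}
    sex_tot: dict = {}
    grand = np.zeros(n)
    for j, row in enumerate(cost_df.itertuples(index=False)):
        if not row.available:
            continue
        cost_usd = cost_mat[:, j]
        if row.currency == "CRC":
            cost_usd = cost_usd / bundle.currency.crc_per_usd
        attr = af_sex[(row.disease, row.sex)] / 100.0 * cost_usd
        draws[f"cell::{row.disease}::{row.service}::{row.sex}"] = attr
        service_tot[row.service] = service_tot.get(row.service, 0.0) + attr
        disease_tot[row.disease] = disease_tot.get(row.disease, 0.0) + attr
        sex_tot[row.sex] = sex_tot.get(row.sex, 0.0) + attr
        grand = grand + attr
    draws["direct_total"] = grand
    for k, v in service_tot.items():
        draws[f"service::{k}"] = v
    for k, v in disease_tot.items():
        draws[f"disease::{k}"] = v
    for k, v in sex_tot.items():
        draws[f"sex::{k}"] = v

    # --- productivity losses (human-capital approach)
    labor = bundle.labor
    annual_value = labor.monthly_wage * labor.annualization_factor * labor.participation_rate
    prod_outcome: dict = {}
    prod_sex: dict = {}
    prod_cell: dict = {}
    yll_tot = np.zeros(n)
    ypll_tot = np.zeros(n)
    loss_tot = np.zeros(n)
    for row in bundle.mortality.itertuples(index=False):
        if settings.mortality_kind == "total":
            frac = af_stratum.get((row.outcome, row.sex, row.age_group))
            if frac is None:
                raise KeyError(
                    f"no RR record for mortality stratum "
                    f"({row.outcome}, {row.sex}, {row.age_group})"
                )
            deaths = np.clip(frac, 0.0, 100.0) / 100.0 * row.n_deaths
        else:
            deaths = np.full(n, float(row.n_deaths))
        per_death_wyl = min(
            working_years_lost(row.age_at_death, row.sex, labor),
            row.residual_life_expectancy,
        )
        yll_r = deaths * row.residual_life_expectancy
        ypll_r = deaths * per_death_wyl
        loss_r = ypll_r * annual_value
        yll_tot += yll_r
        ypll_tot += ypll_r
        loss_tot += loss_r
        prod_outcome[row.outcome] = prod_outcome.get(row.outcome, 0.0) + loss_r
        prod_sex[row.sex] = prod_sex.get(row.sex, 0.0) + loss_r
        key = (row.outcome, row.sex)
        prod_cell[key] = prod_cell.get(key, 0.0) + loss_r
    draws["yll_total"] = yll_tot
    draws["ypll_total"] = ypll_tot
    draws["productivity_total"] = loss_tot
    for k, v in prod_outcome.items():
        draws[f"productivity::{k}"] = v
    for k, v in prod_sex.items():
        draws[f"productivity_sex::{k}"] = v
    for (o, s), v in prod_cell.items():
        draws[f"productivity_cell::{o}::{s}"] = v

    draws = {k: np.asarray(np.broadcast_to(v, (n,))) for k, v in draws.items()}
    return ModelOutputs(draws=draws, n_draws=n)


@dataclass
class DeterministicResult:
    """Point-estimate run: per-stratum PAF table, attributable-cost cells,
    aggregated report tables and productivity results."""

    paf: pd.DataFrame
    cells: list
    report: object
    productivity: list
    productivity_tables: tuple
    outputs: ModelOutputs


def run_deterministic(bundle: InputBundle,
                      settings: ModelSettings | None = None) -> DeterministicResult:
    """One point-estimate evaluation with tidy result containers."""
    settings = settings or ModelSettings()
    out = compute_model(bundle, settings)

    paf_rows = []
    for row in bundle.rr_table.itertuples(index=False):
        key = f"{row.outcome}::{row.sex}::{row.age_group}"
        paf_rows.append(
            (
                row.outcome, row.sex, row.age_group,
                out.scalar(f"P::{key}"),
                out.scalar(f"RR::{key}"),
                out.scalar(f"par_baseline::{key}"),
                out.scalar(f"par_baseline::{key}") - out.scalar(f"par::{key}"),
                out.scalar(f"par::{key}"),
            )
        )
    paf = pd.DataFrame(
        paf_rows,
        columns=["outcome", "sex", "age_group", "P", "RR",
                 "PAR_baseline", "PAR_counterfactual", "PAR_attributable"],
    )

    cells = []
    for row in bundle.cost_table.itertuples(index=False):
        if not row.available:
            continue
        cells.append(
            AttributableCost(
                disease=row.disease, service=row.service, sex=row.sex,
                point=out.scalar(f"cell::{row.disease}::{row.service}::{row.sex}"),
            )
        )
    report = aggregate(cells)

    labor = bundle.labor
    prod_results = []
    for row in bundle.mortality.itertuples(index=False):
        if settings.mortality_kind == "total":
            frac = out.scalar(f"par::{row.outcome}::{row.sex}::{row.age_group}")
            deaths = max(min(frac, 100.0), 0.0) / 100.0 * row.n_deaths
        else:
            deaths = float(row.n_deaths)
        per_death_wyl = min(
            working_years_lost(row.age_at_death, row.sex, labor),
            row.residual_life_expectancy,
        )
        ypll = deaths * per_death_wyl
        prod_results.append(
            ProductivityResult(
                outcome=row.outcome,
                stratum=Stratum(sex=row.sex, age_group=row.age_group),
                yll=deaths * row.residual_life_expectancy,
                ypll=ypll,
                loss=ypll * labor.monthly_wage * labor.annualization_factor
                * labor.participation_rate,
            )
        )
    prod_tables = productivity_report(prod_results)

    return DeterministicResult(
        paf=paf,
        cells=cells,
        report=report,
        productivity=prod_results,
        productivity_tables=prod_tables,
        outputs=out,
    )
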