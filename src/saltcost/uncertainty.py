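"""Monte Carlo propagation of input uncertainty through the full pipeline.

Each of the 10,000 default draws resamples the three uncertain input classes
— the population mean salt intake, every available cost cell, and every
per-mmHg relative risk — from log-normal distributions, re-runs the whole
exposure → risk → costs → productivity chain, and records every model
output.  Point estimates are the median of draws; 95% uncertainty intervals
are the 2.5th and 97.5th percentiles (order statistics with linear
interpolation, numpy's default).

Sampling distributions:

* mean intake and cost cells: log-normal matched by the method of moments
  to (value, relative SE × value);
* relative risks: ln RR ~ Normal(ln RR₀, se) with se = 10% of |ln RR₀|
  unless a standard error is supplied.

Each input cell owns a counter-based substream derived from the one global
seed and a stable label hash, so adding or removing an output never
perturbs the other streams.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import ModelSettings, compute_model
from .synthetic_inputs import InputBundle

__all__ = ["MCConfig", "MCSummary", "lognormal_params", "sample_lognormal",
           "percentile_interval", "run_monte_carlo"]


@dataclass(frozen=True)
class MCConfig:
    """Monte Carlo settings.

    Relative standard errors parameterise the input sampling distributions;
    the source tables publish point values only, so these are explicit
    modelling choices (10% by default), not published dispersions.  Setting
    them all to zero degenerates every draw to the point estimate.
    """

    draws: int = 10_000
    seed: int = 0
    ui_level: float = 0.95
    intake_rel_se: float = 0.10
    cost_rel_se: float = 0.10
    rr_log_se_frac: float = 0.10

    def __post_init__(self) -> None:
        if self.draws < 1:
            raise ValueError("draws must be >= 1")
        if not 0.0 < self.ui_level < 1.0:
            raise ValueError("ui_level must be in (0, 1)")
        for attr in ("intake_rel_se", "cost_rel_se", "rr_log_se_frac"):
            if getattr(self, attr) < 0:
                raise ValueError(f"{attr} must be >= 0")


@dataclass
class MCSummary:
    """Per-quantity point (median of draws) and percentile interval."""

    table: pd.DataFrame  # index: quantity; columns: point, ui_low, ui_high
    n_draws: int

    def point(self, name: str) -> float:
        return float(self.table.loc[name, "point"])

    def interval(self, name: str) -> tuple[float, float]:
        row = self.table.loc[name]
        return float(row["ui_low"]), float(row["ui_high"])


def lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """Method-of-moments log-normal parameters for a given mean and SD.

    sigma² = ln(1 + sd²/mean²), mu = ln(mean) − sigma²/2; sd = 0 gives the
    degenerate (ln mean, 0).
    """
    if not mean > 0:
        raise ValueError(f"mean must be > 0, got {mean}")
    if sd < 0:
        raise ValueError("sd must be >= 0")
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return float(mu), float(np.sqrt(sigma2))


def sample_lognormal(rng: np.random.Generator, mean: float, sd: float,
                     size: int) -> np.ndarray:
    """Log-normal draws with the requested first two moments."""
    mu, sigma = lognormal_params(mean, sd)
    if sigma == 0.0:
        return np.full(size, mean)
    return rng.lognormal(mean=mu, sigma=sigma, size=size)


def percentile_interval(samples, level: float = 0.95) -> tuple[float, float]:
    """Central percentile interval by sort-and-linear-interpolation.

    With n samples the p-th percentile sits at rank (n−1)·p (0-based) and is
    linearly interpolated between the bracketing order statistics.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.size == 0:
        raise ValueError("samples must be non-empty")
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    alpha = (1.0 - level) / 2.0
    low, high = np.percentile(samples, [100.0 * alpha, 100.0 * (1.0 - alpha)],
                              method="linear")
    return float(low), float(high)


def _substream(seed: int, label: str) -> np.random.Generator:
    """Independent generator keyed by (global seed, stable label hash)."""
    key = zlib.crc32(label.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([seed, key]))


def run_monte_carlo(bundle: InputBundle, config: MCConfig | None = None,
                    settings: ModelSettings | None = None,
                    trace: bool = False):
    """Propagate input uncertainty through the full model.

    Returns an :class:`MCSummary`; with ``trace=True`` returns
    ``(summary, draws_frame)`` where the frame holds every draw of every
    output for audit.
    Deterministic for a fixed ``config.seed``.
    """
    config = config or MCConfig()
    settings = settings or ModelSettings()
    n = config.draws

    # intake: uncertainty on the population mean; per-person SD stays fixed
    # in the discretisation so prevalence semantics are preserved.
    rng = _substream(config.seed, "intake::baseline::mean")
    intake_means = sample_lognormal(
        rng, bundle.baseline.mean, config.intake_rel_se * bundle.baseline.mean, n
    )

    rr_df = bundle.rr_table.reset_index(drop=True)
    rr_mat = np.empty((n, len(rr_df)))
    for j, row in enumerate(rr_df.itertuples(index=False)):
        label = f"rr::{row.outcome}::{row.sex}::{row.age_group}"
        rng = _substream(config.seed, label)
        log_rr = np.log(row.rr_per_mmHg)
        se = config.rr_log_se_frac * abs(log_rr)
        if se == 0.0:
            rr_mat[:, j] = row.rr_per_mmHg
        else:
            rr_mat[:, j] = np.exp(rng.normal(loc=log_rr, scale=se, size=n))

    cost_df = bundle.cost_table.reset_index(drop=True)
    cost_mat = np.empty((n, len(cost_df)))
    for j, row in enumerate(cost_df.itertuples(index=False)):
        if not row.available:
            cost_mat[:, j] = np.nan
            continue
        label = f"cost::{row.disease}::{row.service}::{row.sex}"
        rng = _substream(config.seed, label)
        cost_mat[:, j] = sample_lognormal(
            rng, row.annual_cost, config.cost_rel_se * row.annual_cost, n
        )

    out = compute_model(
        bundle, settings,
        intake_means=intake_means, rr_values=rr_mat, cost_values=cost_mat,
    )

    rows = {}
    for name, arr in out.draws.items():
        low, high = percentile_interval(arr, config.ui_level)
        rows[name] = (float(np.median(arr)), low, high)
    table = pd.DataFrame.from_dict(
        rows, orient="index", columns=["point", "ui_low", "ui_high"]
    )
    table.index.name = "quantity"
    summary = MCSummary(table=table, n_draws=n)
    if trace:
        return summary, pd.DataFrame(out.draws)
    return summary
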