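"""Run configuration: YAML schema, validation and round-tripping.

A config file fully determines one pipeline run: the scenario block
(baseline and counterfactual intake), the bin scheme, the dose-response
slope, labour and currency parameters, Monte Carlo settings, optional paths
to user-supplied tables (fixture defaults are used when absent) and the
output directory.  Validation failures name the offending field path.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .costs import CurrencyRate
from .exposure import BinScheme, DoseResponseSpec, IntakeDistribution
from .model import ModelSettings
from .productivity import LaborParams
from .uncertainty import MCConfig

__all__ = ["RunConfig", "ConfigError", "load_config", "save_config"]


class ConfigError(ValueError):
    """Configuration file is missing, malformed, or violates an invariant."""


@dataclass(frozen=True)
class RunConfig:
    baseline: IntakeDistribution = field(
        default_factory=lambda: IntakeDistribution(10.0, 5.4, 2171.0))
    counterfactual: IntakeDistribution = field(
        default_factory=lambda: IntakeDistribution(5.0, 2.65, 2171.0))
    bins: BinScheme = field(default_factory=BinScheme)
    dose: DoseResponseSpec = field(default_factory=DoseResponseSpec)
    labor: LaborParams = field(default_factory=LaborParams)
    currency: CurrencyRate = field(default_factory=CurrencyRate)
    mc: MCConfig = field(default_factory=MCConfig)
    counterfactual_mode: str = "distribution"
    mortality_kind: str = "total"
    tables_dir: str | None = None      # bundle directory; None → fixture
    output_dir: str = "results"

    def model_settings(self) -> ModelSettings:
        return ModelSettings(
            bins=self.bins, dose=self.dose,
            counterfactual_mode=self.counterfactual_mode,
            mortality_kind=self.mortality_kind,
        )


def _build(section: str, cls, raw: dict):
    try:
        return cls(**raw)
    except TypeError as exc:
        raise ConfigError(f"{section}: {exc}") from exc
    except ValueError as exc:
        raise ConfigError(f"{section}: {exc}") from exc


def load_config(path) -> RunConfig:
    """Load and validate a YAML (or JSON — valid YAML) config file."""
    p = Path(path)
    if not p.exists():
        raise ConfigError(f"config file not found: {p}")
    with open(p, encoding="utf-8") as fh:
        try:
            raw = yaml.safe_load(fh) or {}
        except yaml.YAMLError as exc:
            raise ConfigError(f"cannot parse {p}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError(f"{p}: top level must be a mapping")

    known = {"scenario", "bins", "dose_response", "labor", "currency", "mc",
             "counterfactual_mode", "mortality_kind", "tables_dir", "output_dir"}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown config sections: {sorted(unknown)}")

    scenario = raw.get("scenario", {})
    baseline = _build("scenario.baseline", IntakeDistribution,
                      scenario.get("baseline", {"mean": 10.0, "sd": 5.4,
                                                "kcal_anchor": 2171.0}))
    counterfactual = _build("scenario.counterfactual", IntakeDistribution,
                            scenario.get("counterfactual",
                                         {"mean": 5.0, "sd": 2.65,
                                          "kcal_anchor": 2171.0}))

    bins_raw = raw.get("bins")
    if bins_raw is None:
        bins = BinScheme()
    else:
        try:
            bins = BinScheme.regular(
                start=bins_raw.get("start", 5.0), stop=bins_raw.get("stop", 12.0),
                width=bins_raw.get("width", 1.0), reference=bins_raw.get("reference"),
            )
        except ValueError as exc:
            raise ConfigError(f"bins: {exc}") from exc

    dose = _build("dose_response", DoseResponseSpec, raw.get("dose_response", {}))
    labor = _build("labor", LaborParams, raw.get("labor", {}))
    currency = _build("currency", CurrencyRate, raw.get("currency", {}))
    mc = _build("mc", MCConfig, raw.get("mc", {}))

    tables_dir = raw.get("tables_dir")
    if tables_dir is not None and not Path(tables_dir).exists():
        raise ConfigError(f"tables_dir: directory not found: {tables_dir}")

    cfg = RunConfig(
        baseline=baseline, counterfactual=counterfactual, bins=bins, dose=dose,
        labor=labor, currency=currency, mc=mc,
        counterfactual_mode=raw.get("counterfactual_mode", "distribution"),
        mortality_kind=raw.get("mortality_kind", "total"),
        tables_dir=tables_dir, output_dir=raw.get("output_dir", "results"),
    )
    if cfg.counterfactual_mode not in ("distribution", "threshold"):
        raise ConfigError(
            f"counterfactual_mode: unknown value {cfg.counterfactual_mode!r}")
    if cfg.mortality_kind not in ("total", "attributable"):
        raise ConfigError(f"mortality_kind: unknown value {cfg.mortality_kind!r}")
    return cfg


def config_dict(cfg: RunConfig) -> dict:
    """Canonical mapping representation (what save_config writes)."""
    return {
        "scenario": {
            "baseline": {"mean": cfg.baseline.mean, "sd": cfg.baseline.sd,
                         "kcal_anchor": cfg.baseline.kcal_anchor},
            "counterfactual": {"mean": cfg.counterfactual.mean,
                               "sd": cfg.counterfactual.sd,
                               "kcal_anchor": cfg.counterfactual.kcal_anchor},
        },
        "bins": {"start": cfg.bins.edges[0], "stop": cfg.bins.edges[-1],
                 "width": cfg.bins.edges[1] - cfg.bins.edges[0]
                 if len(cfg.bins.edges) > 1 else 1.0,
                 "reference": cfg.bins.reference_value},
        "dose_response": asdict(cfg.dose),
        "labor": asdict(cfg.labor),
        "currency": asdict(cfg.currency),
        "mc": asdict(cfg.mc),
        "counterfactual_mode": cfg.counterfactual_mode,
        "mortality_kind": cfg.mortality_kind,
        "tables_dir": cfg.tables_dir,
        "output_dir": cfg.output_dir,
    }


def save_config(cfg: RunConfig, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(config_dict(cfg), fh, sort_keys=True)
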