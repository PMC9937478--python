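"""End-to-end run: load inputs, evaluate the model, propagate uncertainty,
write reports.

Outputs (CSV + JSON) mirror the canonical result tables: attributable direct
costs by disease × service, per-service sex splits, percentage shares, and
productivity losses by outcome × sex, each with 95% uncertainty intervals
from the Monte Carlo engine.  A run log records the config hash, seed and
package version so any result file can be reproduced; runs with the same
config and seed produce byte-identical files.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .config import RunConfig, config_dict
from .costs import render_thousands
from .model import DeterministicResult, run_deterministic
from .synthetic_inputs import InputBundle, default_fixture
from .uncertainty import MCSummary, run_monte_carlo

__all__ = ["PipelineResult", "run_pipeline", "bundle_from_config"]


@dataclass
class PipelineResult:
    deterministic: DeterministicResult
    mc: MCSummary
    output_dir: Path | None


def bundle_from_config(cfg: RunConfig) -> InputBundle:
    """Materialise the input bundle: user tables if given, else the fixture;
    the config's scenario/labour/currency blocks override the bundle's."""
    if cfg.tables_dir is not None:
        from .tables import load_bundle

        bundle = load_bundle(cfg.tables_dir)
    else:
        bundle = default_fixture()
    return bundle.with_(
        baseline=cfg.baseline,
        counterfactual=cfg.counterfactual,
        labor=cfg.labor,
        currency=cfg.currency,
    )


def _config_hash(cfg: RunConfig) -> str:
    # output_dir is where results land, not what determines them
    d = config_dict(cfg)
    d.pop("output_dir", None)
    canonical = yaml.safe_dump(d, sort_keys=True)
    return hashlib.sha256(canonical.encode("utf-8")).hexdigest()


def _write_csv(df: pd.DataFrame, path: Path, index: bool = True) -> None:
    df.to_csv(path, index=index, float_format="%.6f")


def run_pipeline(cfg: RunConfig, write: bool = True) -> PipelineResult:
    """Deterministic evaluation plus Monte Carlo uncertainty; optionally
    write all report files under ``cfg.output_dir``."""
    bundle = bundle_from_config(cfg)
    settings = cfg.model_settings()

    det = run_deterministic(bundle, settings)
    mc = run_monte_carlo(bundle, cfg.mc, settings)

    out_dir: Path | None = None
    if write:
        out_dir = Path(cfg.output_dir)
        out_dir.mkdir(parents=True, exist_ok=True)

        _write_csv(det.paf, out_dir / "paf_by_stratum.csv", index=False)

        cells = det.report.cells.copy()
        intervals = []
        for row in cells.itertuples(index=False):
            name = f"cell::{row.disease}::{row.service}::{row.sex}"
            lo, hi = mc.interval(name)
            intervals.append((lo, hi))
        cells[["ui_low", "ui_high"]] = intervals
        _write_csv(cells, out_dir / "attributable_costs.csv", index=False)

        _write_csv(det.report.disease_by_service,
                   out_dir / "costs_by_disease_service.csv")
        _write_csv(render_thousands(det.report.disease_by_service),
                   out_dir / "costs_by_disease_service_thousands.csv")
        for service, table in det.report.sex_tables.items():
            _write_csv(table, out_dir / f"costs_{service}_by_sex.csv")

        prod_table, outcome_shares, sex_shares, totals = det.productivity_tables
        _write_csv(prod_table, out_dir / "productivity_by_outcome_sex.csv")

        _write_csv(mc.table, out_dir / "mc_summary.csv")

        shares = {
            "service_shares_pct": det.report.service_shares.to_dict(),
            "disease_shares_pct": det.report.disease_shares.to_dict(),
            "sex_shares_pct": {k: v.to_dict() for k, v in det.report.sex_shares.items()},
            "productivity_outcome_shares_pct": outcome_shares.to_dict(),
            "productivity_sex_shares_pct": sex_shares.to_dict(),
            "grand_total_usd": det.report.grand_total,
            "productivity_totals": totals,
            "excluded_cells": [list(x) for x in det.report.excluded],
        }
        with open(out_dir / "summary.json", "w", encoding="utf-8") as fh:
            json.dump(shares, fh, indent=2, sort_keys=True, default=int)

        log = {
            "config_hash": _config_hash(cfg),
            "seed": cfg.mc.seed,
            "draws": cfg.mc.draws,
            "saltcost_version": __version__,
        }
        with open(out_dir / "run_log.json", "w", encoding="utf-8") as fh:
            json.dump(log, fh, indent=2, sort_keys=True)

    return PipelineResult(deterministic=det, mc=mc, output_dir=out_dir)
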