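"""Relative risks and the population attributable risk (PAR).

Per-mmHg relative risks of a cardiovascular outcome are rescaled to intake
bins through the salt→SBP dose response using log-linear exponentiation
(``RR_bin = rr_per_mmHg ** ΔSBP``), the standard comparative-risk-assessment
convention.  The combined relative risk across the exposure distribution is
the prevalence-weighted arithmetic mean of the per-bin RRs among exposed
bins; with that definition the binary formula

    PAR = 100 · P(RR − 1) / (P(RR − 1) + 1)

is algebraically identical to the multi-category attributable fraction
100·Σpᵢ(RRᵢ−1)/(Σpᵢ(RRᵢ−1)+1), because P·(RR̄−1) = Σᵢ pᵢ(RRᵢ−1) when
RR̄ = Σpᵢ RRᵢ / Σpᵢ over the exposed categories.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .exposure import BinScheme, DoseResponseSpec, ExposurePrevalence, sbp_shift
from .strata import Stratum

__all__ = ["RRRecord", "PAFResult", "rr_at_bin", "combined_rr", "par",
           "ProtectiveExposureWarning"]

OUTCOMES = ("CHD", "stroke", "hypertensive", "RHD")


class ProtectiveExposureWarning(UserWarning):
    """Raised when RR < 1 makes the attributable fraction negative."""


@dataclass(frozen=True)
class RRRecord:
    """Relative risk of one CVD outcome per 1 mmHg higher SBP, for one stratum."""

    outcome: str
    stratum: Stratum
    rr_per_mmHg: float

    def __post_init__(self) -> None:
        if not self.rr_per_mmHg > 0:
            raise ValueError(f"rr_per_mmHg must be > 0, got {self.rr_per_mmHg}")


@dataclass(frozen=True)
class PAFResult:
    """Exposure prevalence P, combined relative risk RR, and PAR (%) for one
    stratum × outcome."""

    outcome: str
    stratum: Stratum
    P: float
    RR: float
    PAR: float


def rr_at_bin(record: RRRecord, bin_midpoint: float, reference: float,
              spec: DoseResponseSpec = DoseResponseSpec()) -> float:
    """Relative risk at one intake bin relative to the reference intake.

    The SBP difference implied by ``bin_midpoint - reference`` exponentiates
    the per-mmHg risk ratio; equals 1 exactly at the reference.
    """
    if not record.rr_per_mmHg > 0:
        raise ValueError("rr_per_mmHg must be > 0")
    delta_sbp = sbp_shift(bin_midpoint - reference, spec)
    return float(record.rr_per_mmHg ** delta_sbp)


def combined_rr(prev: ExposurePrevalence, per_bin_rr) -> tuple[float, float]:
    """Collapse per-bin RRs to the binary (P, RR) pair.

    P is the total mass in exposed (above-reference) bins; RR is the
    mass-weighted mean of per-bin RRs over those bins, with weights
    renormalised.  An unexposed population returns (0, 1) by convention.
    The first bin is the reference and must carry RR = 1.
    """
    masses = np.asarray(prev.masses, dtype=float)
    rrs = np.asarray(per_bin_rr, dtype=float)
    if masses.shape != rrs.shape:
        raise ValueError(f"masses ({masses.shape}) and RRs ({rrs.shape}) must align")
    if abs(rrs[0] - 1.0) > 1e-12:
        raise ValueError("reference bin must have RR = 1")
    P = float(masses[1:].sum())
    if P == 0.0:
        return 0.0, 1.0
    RR = float(np.dot(masses[1:], rrs[1:]) / P)
    return P, RR


def par(P: float, RR: float) -> float:
    """Population attributable risk, in percent: 100·P(RR−1)/(P(RR−1)+1)."""
    if not 0.0 <= P <= 1.0:
        raise ValueError(f"P must be in [0, 1], got {P}")
    if not RR > 0:
        raise ValueError(f"RR must be > 0, got {RR}")
    excess = P * (RR - 1.0)
    denom = excess + 1.0
    if denom == 0.0:
        raise ZeroDivisionError("P(RR-1) = -1: attributable fraction undefined")
    value = 100.0 * excess / denom
    if value < 0:
        warnings.warn(
            f"protective exposure (RR={RR} < 1) yields negative PAR {value:.3f}%",
            ProtectiveExposureWarning,
            stacklevel=2,
        )
    return value


def paf_for_stratum(record: RRRecord, prev: ExposurePrevalence, bins: BinScheme,
                    spec: DoseResponseSpec = DoseResponseSpec()) -> PAFResult:
    """Convenience chain: per-bin RRs → combined (P, RR) → PAR for one stratum."""
    rrs = [rr_at_bin(record, m, bins.reference_value, spec) for m in bins.midpoints]
    P, RR = combined_rr(prev, rrs)
    return PAFResult(outcome=record.outcome, stratum=record.stratum,
                     P=P, RR=RR, PAR=par(P, RR))
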