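"""Population salt-intake exposure: distributions, binning, and the salt→SBP link.

The population's daily salt intake is summarised by a mean and standard
deviation (g/person/day) and modelled as a normal distribution truncated at
zero (negative intake is impossible; with mean 10 and SD 5.4 the untruncated
normal puts ~3% of mass below zero).  The continuous intake axis is cut into
1 g/day bins from the WHO reference of 5 g/day up to an open ">= last edge"
tail, and each bin's probability mass becomes the prevalence of that level of
exposure.  Salt differences map linearly onto systolic blood pressure (SBP)
differences via a dose-response slope (default: a 6 g/day salt reduction
lowers SBP by 5.8 mmHg).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

__all__ = [
    "IntakeDistribution",
    "DoseResponseSpec",
    "BinScheme",
    "ExposurePrevalence",
    "discretize",
    "bin_mass_matrix",
    "sbp_shift",
    "excess_prevalence",
]


@dataclass(frozen=True)
class IntakeDistribution:
    """Population salt intake in g/person/day, as mean +/- SD.

    ``kcal_anchor`` records the average caloric intake the survey adjusted
    to; it is metadata only and enters no computation.
    """

    mean: float
    sd: float
    kcal_anchor: float | None = None

    def __post_init__(self) -> None:
        if not self.mean > 0:
            raise ValueError(f"intake mean must be > 0, got {self.mean}")
        if self.sd < 0:
            raise ValueError(f"intake sd must be >= 0, got {self.sd}")


@dataclass(frozen=True)
class DoseResponseSpec:
    """Linear salt→SBP dose response: ``sbp_drop_mmHg`` per ``per_salt_drop_g``."""

    sbp_drop_mmHg: float = 5.8
    per_salt_drop_g: float = 6.0

    def __post_init__(self) -> None:
        if not (self.sbp_drop_mmHg > 0 and self.per_salt_drop_g > 0):
            raise ValueError("dose-response parameters must be strictly positive")


@dataclass(frozen=True)
class BinScheme:
    """Intake bins: an open bin below the first edge, unit bins between edges,
    and an open bin above the last edge.

    The bin below ``reference_value`` (the WHO 5 g/day limit by default) is the
    unexposed reference category.  The open top bin is represented by the last
    edge plus half the interior bin width.
    """

    edges: tuple[float, ...] = (5.0, 6.0, 7.0, 8.0, 9.0, 10.0, 11.0, 12.0)
    reference_value: float = 5.0

    def __post_init__(self) -> None:
        e = np.asarray(self.edges, dtype=float)
        if e.size < 1 or np.any(np.diff(e) <= 0):
            raise ValueError("bin edges must be strictly increasing")
        if self.reference_value > e[0]:
            raise ValueError(
                f"reference_value {self.reference_value} must not exceed first edge {e[0]}"
            )
        object.__setattr__(self, "edges", tuple(float(x) for x in e))

    @property
    def n_bins(self) -> int:
        return len(self.edges) + 1

    @property
    def midpoints(self) -> np.ndarray:
        """Representative intake per bin; the reference bin maps to the
        reference value itself (its SBP shift, hence excess risk, is zero)."""
        e = np.asarray(self.edges)
        width = e[-1] - e[-2] if len(e) > 1 else 1.0
        mids = np.empty(self.n_bins)
        mids[0] = self.reference_value
        mids[1:-1] = 0.5 * (e[:-1] + e[1:])
        mids[-1] = e[-1] + 0.5 * width
        return mids

    @classmethod
    def regular(cls, start: float = 5.0, stop: float = 12.0, width: float = 1.0,
                reference: float | None = None) -> "BinScheme":
        edges = tuple(np.arange(start, stop + 0.5 * width, width))
        return cls(edges=edges, reference_value=start if reference is None else reference)


@dataclass(frozen=True)
class ExposurePrevalence:
    """Per-bin probability mass of the intake distribution."""

    masses: tuple[float, ...]
    midpoints: tuple[float, ...] = field(default=())

    def __post_init__(self) -> None:
        m = np.asarray(self.masses, dtype=float)
        if np.any(m < -1e-12):
            raise ValueError("bin masses must be non-negative")
        if abs(m.sum() - 1.0) > 1e-9:
            raise ValueError(f"bin masses must sum to 1, got {m.sum():.12f}")
        if self.midpoints and len(self.midpoints) != len(self.masses):
            raise ValueError("one midpoint per bin required")


def bin_mass_matrix(means, sd: float, bins: BinScheme) -> np.ndarray:
    """Probability mass per bin for zero-truncated normal intake.

    ``means`` may be a scalar or an array; the result has shape
    ``means.shape + (n_bins,)``, so the Monte Carlo engine can evaluate many
    sampled means in one vectorised call.  ``sd == 0`` gives a degenerate
    distribution: all mass in the bin containing the mean.
    """
    means = np.atleast_1d(np.asarray(means, dtype=float))
    if np.any(means <= 0):
        raise ValueError("intake mean must be > 0")
    if sd < 0:
        raise ValueError("intake sd must be >= 0")
    edges = np.asarray(bins.edges)
    k = bins.n_bins
    out = np.zeros(means.shape + (k,))
    if sd == 0:
        idx = np.searchsorted(edges, means, side="right")
        np.put_along_axis(out, idx[..., None], 1.0, axis=-1)
        return out
    # CDF at [-inf, e0, ..., eK, +inf], renormalised over the mass above 0
    z = (edges[None, :] - means[:, None]) / sd
    cdf = norm.cdf(z)
    below0 = norm.cdf(-means / sd)[:, None]
    denom = 1.0 - below0
    # cumulative mass up to each edge, truncated at 0 and renormalised
    cum = np.concatenate(
        [np.zeros((means.shape[0], 1)),
         np.clip((cdf - below0) / denom, 0.0, 1.0),
         np.ones((means.shape[0], 1))],
        axis=1,
    )
    out = np.diff(cum, axis=1)
    return out


def discretize(dist: IntakeDistribution, bins: BinScheme) -> ExposurePrevalence:
    """Cut an intake distribution into the bin scheme's prevalence vector."""
    masses = bin_mass_matrix(dist.mean, dist.sd, bins)[0]
    return ExposurePrevalence(masses=tuple(masses), midpoints=tuple(bins.midpoints))


def sbp_shift(delta_salt: float, spec: DoseResponseSpec = DoseResponseSpec()) -> float:
    """SBP difference (mmHg) for a salt-intake difference (g/day); linear and odd."""
    return delta_salt * spec.sbp_drop_mmHg / spec.per_salt_drop_g


def excess_prevalence(prev: ExposurePrevalence, bins: BinScheme) -> float:
    """Total probability mass above the reference bin (the exposed fraction P)."""
    return float(np.sum(np.asarray(prev.masses)[1:]))
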