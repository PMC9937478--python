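"""Population strata: sex × 5-year age band from 15–19 upwards."""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["SEXES", "Stratum", "default_age_bands", "age_band_midpoint"]

SEXES = ("male", "female")

#: 5-year bands from 15–19 through 75–79 plus an open 80+ band (GBD convention).
DEFAULT_AGE_BANDS = tuple(f"{a}-{a + 4}" for a in range(15, 80, 5)) + ("80+",)

#: representative age used for the open 80+ band
OPEN_BAND_MIDPOINT = 85.0


@dataclass(frozen=True, order=True)
class Stratum:
    """One sex × age-group cell of the adult (15+) population."""

    sex: str
    age_group: str

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}, got {self.sex!r}")


def default_age_bands() -> tuple[str, ...]:
    return DEFAULT_AGE_BANDS


def age_band_midpoint(age_group: str) -> float:
    """Midpoint age of a '<lo>-<hi>' band; the open '<lo>+' band maps to 85."""
    if age_group.endswith("+"):
        return OPEN_BAND_MIDPOINT
    lo, hi = age_group.split("-")
    return (float(lo) + float(hi) + 1.0) / 2.0


def validate_age_bands(bands) -> None:
    """Bands must be disjoint, ordered, and start at 15 with an open last band."""
    prev_hi = None
    for i, b in enumerate(bands):
        is_last = i == len(bands) - 1
        if b.endswith("+"):
            if not is_last:
                raise ValueError(f"open band {b!r} must be last")
            lo = float(b[:-1])
            hi = None
        else:
            lo_s, hi_s = b.split("-")
            lo, hi = float(lo_s), float(hi_s)
            if hi < lo:
                raise ValueError(f"band {b!r} is inverted")
        if prev_hi is not None and lo != prev_hi + 1:
            raise ValueError(f"bands not contiguous at {b!r}")
        if prev_hi is None and lo != 15:
            raise ValueError(f"first band must start at 15, got {b!r}")
        prev_hi = hi
    if prev_hi is not None:
        raise ValueError("last band must be open-ended (e.g. '80+')")
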