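"""Cancer-specific age-band schemas and representative-age rules.

Registry extracts for each cancer site arrive aggregated into a small number
of site-specific age bands (surveillance convention: oral cancer uses three
broad bands, the screening-target sites four).  A band is a half-open
interval ``[age_lo, age_hi]`` in completed years, with the terminal band
open-ended (``age_hi = inf``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np

#: Cancer sites covered by the national screening programmes.
CANCER_SITES = ("BC", "CxCa", "OC", "CRC")

#: Sites restricted to the female population (breast and cervical cancer).
FEMALE_SITES = frozenset({"BC", "CxCa"})

#: AJCC stages used throughout (stage 0 = in situ).
STAGES = ("0", "I", "II", "III", "IV")

#: Offset added to the lower bound of the open terminal band to obtain its
#: representative age (midpoint is undefined for an open interval).
OPEN_BAND_OFFSET = 7.5


@dataclass(frozen=True)
class AgeBandSchema:
    """Ordered, contiguous age bands for one cancer site.

    ``bands`` is a tuple of ``(lower, upper)`` pairs, both inclusive in
    completed years; the final band has ``upper = math.inf``.
    """

    cancer_site: str
    bands: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if not self.bands:
            raise ValueError("schema needs at least one band")
        if self.bands[0][0] != 0:
            raise ValueError(f"{self.cancer_site}: first band must start at age 0")
        if not math.isinf(self.bands[-1][1]):
            raise ValueError(f"{self.cancer_site}: final band must be open-ended")
        for (lo, hi), (nlo, _) in zip(self.bands, self.bands[1:]):
            if math.isinf(hi):
                raise ValueError(f"{self.cancer_site}: open band must be last")
            if nlo != hi + 1:
                raise ValueError(
                    f"{self.cancer_site}: bands must be contiguous, "
                    f"got upper {hi} followed by lower {nlo}"
                )

    @property
    def lowers(self) -> np.ndarray:
        return np.array([lo for lo, _ in self.bands], dtype=float)

    @property
    def uppers(self) -> np.ndarray:
        return np.array([hi for _, hi in self.bands], dtype=float)

    def band_of(self, age: float) -> tuple[float, float]:
        """Return the (lo, hi) band containing ``age``."""
        for lo, hi in self.bands:
            if lo <= age <= hi:
                return (lo, hi)
        raise ValueError(f"age {age} outside schema for {self.cancer_site}")


def _schema(site: str, *cuts: float) -> AgeBandSchema:
    """Build a schema from lower cut-points, e.g. (40, 60) -> 0-39/40-59/60+."""
    lowers = (0.0, *map(float, cuts))
    uppers = (*(c - 1.0 for c in lowers[1:]), math.inf)
    return AgeBandSchema(site, tuple(zip(lowers, uppers)))


#: Surveillance band schema per cancer site.
SITE_SCHEMAS: dict[str, AgeBandSchema] = {
    "OC": _schema("OC", 40, 60),
    "CRC": _schema("CRC", 50, 70),
    "BC": _schema("BC", 35, 50, 70),
    "CxCa": _schema("CxCa", 30, 50, 70),
}


def midpoint_representative_age(age_lo: float, age_hi: float) -> float:
    """Representative single age of a band, for life-table lookups.

    Closed bands use the midpoint of the covered year-interval
    ``[lo, hi + 1)``; the open terminal band uses ``lo + OPEN_BAND_OFFSET``.
    """
    if math.isinf(age_hi):
        return age_lo + OPEN_BAND_OFFSET
    return (age_lo + age_hi + 1.0) / 2.0


#: Signature of a representative-age rule.
RepresentativeAgeRule = Callable[[float, float], float]
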