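"""Critical-threshold calibration and three-level hazard classification.

Reference samples of actually uprooted trees define the distribution of the
resistance index at failure.  Upper normal bounds of that distribution at
the 95% and 99% levels band standing trees into High / Moderate / Low
uprooting-hazard classes.
"""

from __future__ import annotations

import enum
import math
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .core import Species

__all__ = [
    "Z95",
    "Z99",
    "UprootedReference",
    "HazardThresholds",
    "HazardLevel",
    "StandSummary",
    "critical_thresholds",
    "classify_tree",
    "summarize_stand",
]

#: Two-sided standard-normal quantiles at the 95% and 99% levels.
Z95 = 1.959964
Z99 = 2.575829


class HazardLevel(enum.Enum):
    """Uprooting hazard band; ordering is by hazard, High worst."""

    HIGH = "High"
    MODERATE = "Moderate"
    LOW = "Low"

    def __lt__(self, other: "HazardLevel") -> bool:  # Low < Moderate < High
        order = [HazardLevel.LOW, HazardLevel.MODERATE, HazardLevel.HIGH]
        return order.index(self) < order.index(other)

    @classmethod
    def parse(cls, value: "HazardLevel | str") -> "HazardLevel":
        if isinstance(value, cls):
            return value
        try:
            return cls(str(value).strip().capitalize())
        except ValueError:
            raise ValueError(f"unknown hazard level: {value!r}") from None


@dataclass(frozen=True)
class UprootedReference:
    """Resistance-index reference for uprooted trees of one species.

    Either per-tree index values or a (mean, sd, n) summary must be given;
    values take precedence when both are present.
    """

    species: Species
    values: Optional[tuple[float, ...]] = None
    mean: Optional[float] = None
    sd: Optional[float] = None
    n: Optional[int] = None
    source: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "species", Species.parse(self.species))
        if self.values is not None:
            values = tuple(float(v) for v in self.values)
            if len(values) < 2:
                raise ValueError("at least two reference values are required")
            if not all(math.isfinite(v) and v > 0 for v in values):
                raise ValueError("reference values must be finite and positive")
            object.__setattr__(self, "values", values)
        else:
            if self.mean is None or self.sd is None:
                raise ValueError("either values or (mean, sd) must be supplied")
            if self.sd < 0:
                raise ValueError("sd must be >= 0")
            if self.n is not None and self.n < 2:
                raise ValueError("summary n must be >= 2")

    @property
    def sample_mean(self) -> float:
        if self.values is not None:
            return float(np.mean(self.values))
        return float(self.mean)  # type: ignore[arg-type]

    @property
    def sample_sd(self) -> float:
        if self.values is not None:
            return float(np.std(self.values, ddof=1))
        return float(self.sd)  # type: ignore[arg-type]

    @property
    def sample_n(self) -> Optional[int]:
        if self.values is not None:
            return len(self.values)
        return self.n


@dataclass(frozen=True)
class HazardThresholds:
    """Calibrated (t95, t99) resistance-index bounds.

    High for index ≤ t95, Moderate strictly between, Low at or above t99.
    """

    t95: float
    t99: float
    rounding: int = 2

    def __post_init__(self) -> None:
        if not (math.isfinite(self.t95) and math.isfinite(self.t99)):
            raise ValueError("thresholds must be finite")
        if self.t99 < self.t95:
            raise ValueError(f"t99 ({self.t99}) must be >= t95 ({self.t95})")


def critical_thresholds(
    ref: UprootedReference,
    z95: float = Z95,
    z99: float = Z99,
    rounding: int = 2,
) -> HazardThresholds:
    """Calibrate hazard thresholds from an uprooted-tree reference.

    ``t95 = mean + z95 * sd`` and ``t99 = mean + z99 * sd``, each rounded to
    ``rounding`` decimals before use so that classification of published
    tables is bit-stable.
    """
    if z99 <= z95:
        raise ValueError("z99 must exceed z95")
    mean, sd = ref.sample_mean, ref.sample_sd
    return HazardThresholds(
        t95=round(mean + z95 * sd, rounding),
        t99=round(mean + z99 * sd, rounding),
        rounding=rounding,
    )


def classify_tree(delta_prime: float, thresholds: HazardThresholds) -> HazardLevel:
    """Band one resistance-index value into a :class:`HazardLevel`.

    The boundary value t99 itself is assigned Low (the published example
    labels a tree sitting exactly on t99 as Low, contradicting the prose
    rule "moderate up to and including t99"; the label convention wins).
    """
    if not math.isfinite(delta_prime):
        raise ValueError(f"delta_prime must be finite, got {delta_prime!r}")
    if delta_prime <= thresholds.t95:
        return HazardLevel.HIGH
    if delta_prime < thresholds.t99:
        return HazardLevel.MODERATE
    return HazardLevel.LOW


@dataclass(frozen=True)
class StandSummary:
    """Per-species and total hazard-level counts for a stand."""

    by_species: Mapping[Species, Mapping[HazardLevel, int]]
    totals: Mapping[HazardLevel, int]
    n: int

    def count(self, species: Species, level: HazardLevel) -> int:
        return self.by_species.get(Species.parse(species), {}).get(
            HazardLevel.parse(level), 0
        )


def summarize_stand(
    records: Iterable[tuple["Species | str", float]],
    thresholds: Mapping["Species | str", HazardThresholds],
) -> StandSummary:
    """Classify ``(species, delta_prime)`` records and tally levels.

    Every species occurring in *records* must have an entry in *thresholds*.
    """
    thresholds = {Species.parse(k): v for k, v in thresholds.items()}
    by_species: dict[Species, Counter] = {}
    totals: Counter = Counter()
    n = 0
    for species, value in records:
        species = Species.parse(species)
        if species not in thresholds:
            raise ValueError(f"no thresholds supplied for species {species.value!r}")
        level = classify_tree(float(value), thresholds[species])
        by_species.setdefault(species, Counter())[level] += 1
        totals[level] += 1
        n += 1
    return StandSummary(
        by_species={
            sp: {level: counts.get(level, 0) for level in HazardLevel}
            for sp, counts in by_species.items()
        },
        totals={level: totals.get(level, 0) for level in HazardLevel},
        n=n,
    )
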