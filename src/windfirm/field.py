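"""Field-derived quantities: radar root densities and soil physical properties.

Coarse-root density is roots per unit scanned area on circular transects at
fixed radii around the stem, binned by depth.  Group comparisons use classic
one-way ANOVA followed by Tukey HSD with a compact letter display
(Tukey-Kramer for unbalanced groups).  Soil routines implement gravimetric
water content, core bulk density, and porosity from an assumed particle
density.
"""

from __future__ import annotations

import enum
import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import Species

__all__ = [
    "DepthBin",
    "GPRScanRecord",
    "SoilSample",
    "DensityProfile",
    "TukeyResult",
    "coarse_root_density",
    "density_profile",
    "oneway_anova",
    "tukey_hsd",
    "compact_letters",
    "gravimetric_water_content",
    "bulk_density_from_core",
    "porosity_from_bulk_density",
    "DEFAULT_PARTICLE_DENSITY",
]

DEFAULT_PARTICLE_DENSITY = 2.65  # g·cm⁻³, assumed mineral particle density

#: Transect radii of the scanning design, m.
TRANSECT_RADII = (0.5, 1.0, 1.5, 2.0)


class DepthBin(str, enum.Enum):
    """Vertical scan bins (cm)."""

    D0_15 = "0-15"
    D15_30 = "15-30"
    D30_45 = "30-45"
    DEEP = ">45"

    @classmethod
    def parse(cls, value: "DepthBin | str") -> "DepthBin":
        if isinstance(value, cls):
            return value
        key = str(value).strip().replace("–", "-").replace("~", "-").replace(" ", "")
        for member in cls:
            if key == member.value:
                return member
        raise ValueError(f"unknown depth bin: {value!r}")


#: Bins counted as shallow (0-30 cm) in the depth-distribution summary.
SHALLOW_BINS = frozenset({DepthBin.D0_15, DepthBin.D15_30})


@dataclass(frozen=True)
class GPRScanRecord:
    """One transect x depth-bin scan for one tree.

    ``short_axis`` is the short axis of the radar-formed ellipse for the
    depth bin — the second dimension of the scanned area.  It is a measured
    input; radargram processing is out of scope here.
    """

    tree_id: str
    transect_radius: float
    depth_bin: DepthBin
    scan_length: float
    short_axis: float
    root_count: int
    species: Optional[Species] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "depth_bin", DepthBin.parse(self.depth_bin))
        if self.species is not None:
            object.__setattr__(self, "species", Species.parse(self.species))
        if self.transect_radius <= 0:
            raise ValueError("transect_radius must be positive")
        if self.scan_length <= 0 or self.short_axis <= 0:
            raise ValueError("scan area dimensions must be positive")
        if self.root_count < 0 or self.root_count != int(self.root_count):
            raise ValueError("root_count must be a non-negative integer")


def coarse_root_density(rec: GPRScanRecord) -> float:
    """Roots per m²: count divided by ``scan_length * short_axis``."""
    area = rec.scan_length * rec.short_axis
    if area <= 0:
        raise ValueError("scan area must be positive")
    return rec.root_count / area


@dataclass(frozen=True)
class DensityProfile:
    """Grouped density summaries from a set of scan records.

    ``transect_means`` / ``depth_means`` are DataFrames indexed by
    (species, group) with columns mean, se, n; ``shallow_fraction`` maps
    species to the fraction of detected roots in the 0-30 cm bins.
    """

    transect_means: pd.DataFrame
    depth_means: pd.DataFrame
    shallow_fraction: dict[Species, float]


def _grouped_stats(frame: pd.DataFrame, key: str) -> pd.DataFrame:
    grouped = frame.groupby(["species", key], observed=True)["density"]
    out = grouped.agg(mean="mean", n="count", sd=lambda v: v.std(ddof=1))
    out["se"] = out["sd"] / np.sqrt(out["n"])
    out.loc[out["n"] == 1, "se"] = np.nan
    return out[["mean", "se", "n"]]


def density_profile(records: Iterable[GPRScanRecord]) -> DensityProfile:
    """Mean root density per transect radius and per depth bin, by species.

    Raises if no records are supplied or a species lacks a species label;
    empty groups simply do not appear in the output rather than showing 0.
    """
    records = list(records)
    if not records:
        raise ValueError("no scan records supplied")
    if any(rec.species is None for rec in records):
        raise ValueError("all records need a species label for profiling")
    frame = pd.DataFrame(
        {
            "species": [rec.species for rec in records],
            "transect_radius": [rec.transect_radius for rec in records],
            "depth_bin": [rec.depth_bin.value for rec in records],
            "root_count": [rec.root_count for rec in records],
            "density": [coarse_root_density(rec) for rec in records],
        }
    )
    shallow = {}
    shallow_values = {bin.value for bin in SHALLOW_BINS}
    for species, sub in frame.groupby("species"):
        total = sub["root_count"].sum()
        if total == 0:
            shallow[species] = float("nan")
        else:
            shallow[species] = (
                sub.loc[sub["depth_bin"].isin(shallow_values), "root_count"].sum()
                / total
            )
    return DensityProfile(
        transect_means=_grouped_stats(frame, "transect_radius"),
        depth_means=_grouped_stats(frame, "depth_bin"),
        shallow_fraction=shallow,
    )


# ---------------------------------------------------------------------------
# group comparisons


def _as_groups(groups: Sequence[Sequence[float]]) -> list[np.ndarray]:
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("at least two groups are required")
    for i, arr in enumerate(arrays):
        if arr.ndim != 1 or arr.size < 2:
            raise ValueError(f"group {i} needs at least two observations")
        if not np.all(np.isfinite(arr)):
            raise ValueError(f"group {i} contains non-finite values")
    return arrays


def oneway_anova(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Classical one-way ANOVA; returns ``(F, p)``.

    Degenerate inputs are handled explicitly: zero within-group variance
    with distinct means gives ``(inf, 0.0)``; zero variance everywhere
    gives ``(0.0, 1.0)``.
    """
    arrays = _as_groups(groups)
    grand = np.concatenate(arrays)
    ss_within = sum(float(np.sum((a - a.mean()) ** 2)) for a in arrays)
    ss_between = sum(a.size * (a.mean() - grand.mean()) ** 2 for a in arrays)
    if ss_within == 0.0:
        return (0.0, 1.0) if np.isclose(ss_between, 0.0) else (math.inf, 0.0)
    if np.isclose(ss_between, 0.0):
        return 0.0, 1.0
    stat = stats.f_oneway(*arrays)
    return float(stat.statistic), float(stat.pvalue)


@dataclass(frozen=True)
class TukeyResult:
    """Pairwise Tukey HSD outcome plus a compact letter display.

    ``significant[i, j]`` is True when groups i and j differ at *alpha*;
    ``letters[i]`` is the letter string of group i.  Groups sharing no
    letter are exactly the significantly different pairs.
    """

    pvalues: np.ndarray
    significant: np.ndarray
    letters: tuple[str, ...]
    alpha: float


def compact_letters(significant: np.ndarray) -> tuple[str, ...]:
    """Compact letter display from a boolean significance matrix.

    Insert-and-absorb: start with all groups in one letter column and split
    any column containing a significantly different pair, dropping columns
    absorbed by a superset.  Letters are assigned alphabetically to columns
    ordered by their smallest member.
    """
    significant = np.asarray(significant, dtype=bool)
    k = significant.shape[0]
    columns: list[set[int]] = [set(range(k))]
    for i, j in itertools.combinations(range(k), 2):
        if not significant[i, j]:
            continue
        for col in [c for c in columns if i in c and j in c]:
            columns.remove(col)
            for split in (col - {i}, col - {j}):
                if split and not any(split <= other for other in columns):
                    columns.append(split)
            columns = [
                c
                for c in columns
                if not any(c < other for other in columns if other is not c)
            ]
    columns.sort(key=lambda c: (min(c), sorted(c)))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    labels = [""] * k
    for letter, col in zip(alphabet, columns):
        for member in col:
            labels[member] += letter
    return tuple(labels)


def tukey_hsd(
    groups: Sequence[Sequence[float]], alpha: float = 0.05
) -> TukeyResult:
    """Tukey HSD over *groups* (Tukey-Kramer when unbalanced)."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    arrays = _as_groups(groups)
    result = stats.tukey_hsd(*arrays)
    pvalues = np.asarray(result.pvalue, dtype=float)
    significant = pvalues < alpha
    np.fill_diagonal(significant, False)
    return TukeyResult(
        pvalues=pvalues,
        significant=significant,
        letters=compact_letters(significant),
        alpha=alpha,
    )


# ---------------------------------------------------------------------------
# soil physics


@dataclass(frozen=True)
class SoilSample:
    """One soil-core measurement (masses in g, volume in cm³)."""

    layer: DepthBin
    wet_mass: float
    dry_mass: float
    core_volume: float
    particle_density: float = DEFAULT_PARTICLE_DENSITY

    def __post_init__(self) -> None:
        object.__setattr__(self, "layer", DepthBin.parse(self.layer))
        if self.dry_mass <= 0:
            raise ValueError("dry_mass must be positive")
        if self.wet_mass < self.dry_mass:
            raise ValueError("wet_mass must be >= dry_mass")
        if self.core_volume <= 0:
            raise ValueError("core_volume must be positive")
        if self.particle_density <= 0:
            raise ValueError("particle_density must be positive")


def gravimetric_water_content(sample: SoilSample) -> float:
    """Oven-dry gravimetric water content, percent of dry mass."""
    return 100.0 * (sample.wet_mass - sample.dry_mass) / sample.dry_mass


def bulk_density_from_core(sample: SoilSample) -> float:
    """Dry bulk density of the core, g·cm⁻³."""
    return sample.dry_mass / sample.core_volume


def porosity_from_bulk_density(
    bulk_density: float, particle_density: float = DEFAULT_PARTICLE_DENSITY
) -> float:
    """Total porosity, percent: ``100 * (1 - bulk / particle)``."""
    if bulk_density <= 0:
        raise ValueError("bulk_density must be positive")
    if bulk_density >= particle_density:
        raise ValueError(
            f"bulk density ({bulk_density}) must be below particle density "
            f"({particle_density})"
        )
    return 100.0 * (1.0 - bulk_density / particle_density)
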