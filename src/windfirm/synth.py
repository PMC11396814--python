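"""Synthetic stands, root plates, radar scans, and uprooted-tree references.

Every generator is a pure function of its specification and seed, so the
whole pipeline — morphology → moment balance → classification — can be
exercised end to end without field data.  Morphology marginals default to
the published stand summaries; joint structure is not modelled (independent
truncated normals), which is a documented simplification.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy import optimize, stats

from .core import RootPlateGeometry, Species, TreeMorphology
from .field import DepthBin, GPRScanRecord, TRANSECT_RADII
from .hazard import UprootedReference

__all__ = [
    "MorphologyDistribution",
    "RootPlateDistribution",
    "GPRGradient",
    "StandSpec",
    "Stand",
    "DEFAULT_MORPHOLOGY",
    "generate_stand",
    "generate_gpr_scans",
    "generate_uprooted_reference",
]


@dataclass(frozen=True)
class MorphologyDistribution:
    """Marginal (mean, sd) pairs for the above-ground morphology fields.

    DBH in cm, all lengths in m; crown widths EW/NS share one marginal.
    """

    dbh_mean: float
    dbh_sd: float
    height_mean: float
    height_sd: float
    crown_base_mean: float
    crown_base_sd: float
    crown_width_mean: float
    crown_width_sd: float

    def __post_init__(self) -> None:
        for name in ("dbh_sd", "height_sd", "crown_base_sd", "crown_width_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


#: Stand-summary defaults (per-species mean and SD of the printed samples).
DEFAULT_MORPHOLOGY: dict[Species, MorphologyDistribution] = {
    Species.SPRUCE: MorphologyDistribution(
        dbh_mean=35.1, dbh_sd=5.71,
        height_mean=14.32, height_sd=3.63,
        crown_base_mean=8.41, crown_base_sd=2.95,
        crown_width_mean=7.64, crown_width_sd=2.53,
    ),
    Species.KOREAN_PINE: MorphologyDistribution(
        dbh_mean=42.9, dbh_sd=22.98,
        height_mean=23.9, height_sd=8.22,
        crown_base_mean=12.5, crown_base_sd=4.80,
        crown_width_mean=8.2, crown_width_sd=3.11,
    ),
}


@dataclass(frozen=True)
class RootPlateDistribution:
    """Geometry priors for synthetic root plates.

    No per-sample plate axes are published; the defaults are calibration
    knobs bracketing the volumes implied by the reference table, not claims.
    """

    depth_min: float = 0.3
    depth_max: float = 0.7
    axis_mean: float = 2.0
    axis_sd: float = 0.6
    axis_min: float = 0.2

    def __post_init__(self) -> None:
        if not 0 < self.depth_min < self.depth_max:
            raise ValueError("require 0 < depth_min < depth_max")
        if self.axis_sd < 0 or self.axis_min <= 0:
            raise ValueError("axis_sd must be >= 0 and axis_min > 0")


@dataclass(frozen=True)
class GPRGradient:
    """Intensity structure of synthetic radar scans.

    Expected root count per scan cell is ``base_count`` at the innermost
    transect, decaying as ``exp(-decay * (radius - r0))`` outward, and split
    over depth bins so that ``shallow_fraction`` of roots fall in 0-30 cm
    (peaking at 15-30 cm) with the remainder below.
    """

    base_count: float = 20.0
    decay: float = 0.8
    shallow_fraction: float = 0.72
    shallow_peak_split: float = 0.45  # share of shallow roots in the 0-15 bin
    short_axis: float = 0.15

    def __post_init__(self) -> None:
        if self.base_count < 0:
            raise ValueError("base_count must be >= 0")
        if not 0 <= self.shallow_fraction <= 1:
            raise ValueError("shallow_fraction must be in [0, 1]")
        if not 0 <= self.shallow_peak_split <= 1:
            raise ValueError("shallow_peak_split must be in [0, 1]")
        if self.short_axis <= 0:
            raise ValueError("short_axis must be positive")

    def bin_weights(self) -> dict[DepthBin, float]:
        s = self.shallow_fraction
        return {
            DepthBin.D0_15: s * self.shallow_peak_split,
            DepthBin.D15_30: s * (1.0 - self.shallow_peak_split),
            DepthBin.D30_45: (1.0 - s) * 0.6,
            DepthBin.DEEP: (1.0 - s) * 0.4,
        }


@dataclass(frozen=True)
class StandSpec:
    """Specification of a synthetic mixed stand; ``seed`` is mandatory."""

    seed: int
    n_spruce: int = 0
    n_korean_pine: int = 0
    morphology: Optional[dict[Species, MorphologyDistribution]] = None
    root_plate: RootPlateDistribution = field(default_factory=RootPlateDistribution)
    min_crown_length: float = 0.5

    def __post_init__(self) -> None:
        if self.n_spruce < 0 or self.n_korean_pine < 0:
            raise ValueError("sample sizes must be >= 0")

    def morphology_for(self, species: Species) -> MorphologyDistribution:
        table = self.morphology or DEFAULT_MORPHOLOGY
        return table[species]


@dataclass(frozen=True)
class Stand:
    trees: tuple[TreeMorphology, ...]
    plates: dict[str, RootPlateGeometry]


def _truncated_normal(
    rng: np.random.Generator,
    mean: float,
    sd: float,
    low: float,
    size: int,
    high: float = math.inf,
) -> np.ndarray:
    """Truncated-normal draws via rejection; errors out when the truncation
    region carries essentially no probability mass."""
    if sd == 0:
        if not low < mean < high:
            raise ValueError("degenerate distribution outside truncation region")
        return np.full(size, mean)
    a, b = (low - mean) / sd, (high - mean) / sd
    if stats.norm.cdf(b) - stats.norm.cdf(a) < 1e-12:
        raise ValueError(
            f"truncation region [{low}, {high}] has no mass under "
            f"N({mean}, {sd}^2)"
        )
    out = np.empty(size)
    filled = 0
    while filled < size:
        draw = rng.normal(mean, sd, size=max(size - filled, 16))
        keep = draw[(draw > low) & (draw < high)]
        take = min(keep.size, size - filled)
        out[filled : filled + take] = keep[:take]
        filled += take
    return out


def _draw_trees(
    rng: np.random.Generator,
    species: Species,
    n: int,
    dist: MorphologyDistribution,
    min_crown_length: float,
    prefix: str,
) -> list[TreeMorphology]:
    trees: list[TreeMorphology] = []
    for index in range(n):
        dbh = _truncated_normal(rng, dist.dbh_mean, dist.dbh_sd, 0.0, 1)[0]
        ew = _truncated_normal(rng, dist.crown_width_mean, dist.crown_width_sd, 0.0, 1)[0]
        ns = _truncated_normal(rng, dist.crown_width_mean, dist.crown_width_sd, 0.0, 1)[0]
        # joint rejection keeps height above crown base by the spec margin
        while True:
            height = _truncated_normal(rng, dist.height_mean, dist.height_sd, 0.0, 1)[0]
            base = _truncated_normal(
                rng, dist.crown_base_mean, dist.crown_base_sd, 0.0, 1
            )[0]
            if height - base >= min_crown_length:
                break
        trees.append(
            TreeMorphology(
                tree_id=f"{prefix}{index + 1}",
                species=species,
                dbh=dbh,
                height=height,
                crown_base_height=base,
                crown_width_ew=ew,
                crown_width_ns=ns,
            )
        )
    return trees


def generate_stand(spec: StandSpec) -> Stand:
    """Draw a reproducible synthetic stand (trees plus root-plate geometry)."""
    rng = np.random.default_rng(spec.seed)
    trees: list[TreeMorphology] = []
    trees += _draw_trees(
        rng, Species.SPRUCE, spec.n_spruce,
        spec.morphology_for(Species.SPRUCE), spec.min_crown_length, "S",
    )
    trees += _draw_trees(
        rng, Species.KOREAN_PINE, spec.n_korean_pine,
        spec.morphology_for(Species.KOREAN_PINE), spec.min_crown_length, "K",
    )
    plates: dict[str, RootPlateGeometry] = {}
    rp = spec.root_plate
    for tree in trees:
        depth = rng.uniform(rp.depth_min, rp.depth_max)
        length = _truncated_normal(rng, rp.axis_mean, rp.axis_sd, rp.axis_min, 1)[0]
        width = _truncated_normal(rng, rp.axis_mean, rp.axis_sd, rp.axis_min, 1)[0]
        plates[tree.tree_id] = RootPlateGeometry(
            depth=depth, length=length, width=width
        )
    return Stand(trees=tuple(trees), plates=plates)


def generate_gpr_scans(
    trees: Sequence[TreeMorphology],
    gradient: GPRGradient = GPRGradient(),
    seed: int = 0,
) -> list[GPRScanRecord]:
    """Poisson scan counts over the transect x depth-bin design."""
    rng = np.random.default_rng(seed)
    weights = gradient.bin_weights()
    records: list[GPRScanRecord] = []
    for tree in trees:
        for radius in TRANSECT_RADII:
            scan_length = 2.0 * math.pi * radius
            radial = gradient.base_count * math.exp(
                -gradient.decay * (radius - TRANSECT_RADII[0])
            )
            for depth_bin, weight in weights.items():
                expected = radial * weight
                if expected < 0:
                    raise ValueError("negative expected count")
                records.append(
                    GPRScanRecord(
                        tree_id=tree.tree_id,
                        species=tree.species,
                        transect_radius=radius,
                        depth_bin=depth_bin,
                        scan_length=scan_length,
                        short_axis=gradient.short_axis,
                        root_count=int(rng.poisson(expected)),
                    )
                )
    return records


def _positive_truncnorm_params(mean: float, sd: float) -> tuple[float, float]:
    """Parent (mu, sigma) of a zero-truncated normal whose truncated moments
    equal (mean, sd); reduces to (mean, sd) when truncation is negligible."""

    def moments(params: np.ndarray) -> np.ndarray:
        mu, sigma = params
        if sigma <= 0:
            return np.array([1e6, 1e6])
        a = -mu / sigma
        m, v = stats.truncnorm.stats(a, np.inf, loc=mu, scale=sigma, moments="mv")
        return np.array([m - mean, math.sqrt(v) - sd])

    solution = optimize.root(moments, x0=np.array([mean, sd]), method="hybr")
    if not solution.success:  # pragma: no cover - well-behaved for valid inputs
        raise RuntimeError(f"truncated-normal moment matching failed: {solution.message}")
    mu, sigma = solution.x
    return float(mu), float(sigma)


def generate_uprooted_reference(
    mean: float,
    sd: float,
    n: int,
    seed: int,
    species: "Species | str" = Species.SPRUCE,
) -> UprootedReference:
    """Positive reference sample whose mean and SD converge to (mean, sd).

    Draws come from a zero-truncated normal whose parent parameters are
    moment-matched so the *truncated* distribution has exactly the requested
    mean and SD; thresholds calibrated from a large sample therefore recover
    the summary-based values.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    if sd < 0:
        raise ValueError("sd must be >= 0")
    if mean <= 0:
        raise ValueError("mean must be positive for a positive-valued index")
    rng = np.random.default_rng(seed)
    if sd == 0:
        values = np.full(n, mean)
    else:
        mu, sigma = _positive_truncnorm_params(mean, sd)
        a = -mu / sigma
        values = stats.truncnorm.rvs(
            a, np.inf, loc=mu, scale=sigma, size=n, random_state=rng
        )
    return UprootedReference(
        species=Species.parse(species),
        values=tuple(float(v) for v in values),
        source=f"synthetic(mean={mean}, sd={sd}, n={n}, seed={seed})",
    )
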