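"""Static moment balance for wind-induced tree uprooting.

The model splits a standing conifer into crown, stem, and root plate.
Wind drag on the (conical) crown produces an overturning moment about the
stem base; stem stiffness and the weight of the root plate — a half-ellipsoid
of coarse roots plus enclosed soil — resist it.  The ratio of resistive to
overturning moment is the resistance coefficient ``R_m``; factoring out the
wind-dependent constant ``mu`` leaves the wind-free index ``delta_prime``
used for hazard banding.

All quantities are SI internally (m, kg, N, N·m).  DBH is carried in cm on
the input record, matching field-inventory convention, and converted where
a stem diameter in metres is required.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

__all__ = [
    "GRAVITY",
    "Species",
    "AllometricConvention",
    "TreeMorphology",
    "RootPlateGeometry",
    "RootPlateMass",
    "SpeciesParams",
    "WindParams",
    "SoilLayer",
    "SoilProfile",
    "MomentBreakdown",
    "DEFAULT_SPECIES_PARAMS",
    "DEFAULT_WIND",
    "DEFAULT_SOIL_BULK_DENSITY",
    "species_defaults",
    "crown_radius",
    "crown_frontal_area",
    "wind_load",
    "wind_lever_arm",
    "overturning_moment",
    "stem_resistive_moment",
    "root_plate_volume",
    "soil_mass_in_plate",
    "coarse_root_biomass",
    "root_plate_mass",
    "root_plate_lever_arm",
    "root_plate_resistive_moment",
    "resistance_coefficient",
    "delta_prime",
    "assess_tree",
]

#: Gravitational acceleration, N·kg⁻¹.
GRAVITY = 9.81


class Species(str, enum.Enum):
    """Conifer species handled by the model."""

    SPRUCE = "spruce"
    KOREAN_PINE = "korean_pine"

    @classmethod
    def parse(cls, value: "Species | str") -> "Species":
        if isinstance(value, cls):
            return value
        key = str(value).strip().lower().replace(" ", "_").replace("-", "_")
        aliases = {
            "spruce": cls.SPRUCE,
            "s": cls.SPRUCE,
            "picea": cls.SPRUCE,
            "korean_pine": cls.KOREAN_PINE,
            "koreanpine": cls.KOREAN_PINE,
            "k": cls.KOREAN_PINE,
            "pinus_koraiensis": cls.KOREAN_PINE,
        }
        try:
            return aliases[key]
        except KeyError:
            raise ValueError(f"unknown species: {value!r}") from None


class AllometricConvention(str, enum.Enum):
    """Unit convention under which a coarse-root allometry is evaluated.

    The published coefficient sets do not state their units and turn out to
    differ between species; each convention fixes the diameter unit fed to
    the power law and the scale of its output.  Height is always in metres.
    """

    #: diameter in decimetres, output already in kilograms
    DBH_DM_OUT_KG = "dbh_dm_out_kg"
    #: diameter in centimetres, output in grams (converted to kg on return)
    DBH_CM_OUT_G = "dbh_cm_out_g"


def _require_positive(name: str, value: float) -> float:
    value = float(value)
    if not math.isfinite(value) or value <= 0:
        raise ValueError(f"{name} must be a positive finite number, got {value!r}")
    return value


@dataclass(frozen=True)
class TreeMorphology:
    """Above-ground descriptors of one standing tree.

    Parameters
    ----------
    dbh:
        Stem diameter at breast height, **cm**.
    height:
        Total tree height, m.
    crown_base_height:
        Height from the ground to the crown base, m; must be below ``height``.
    crown_width_ew, crown_width_ns:
        Crown spread along the two cardinal axes, m.
    """

    tree_id: str
    species: Species
    dbh: float
    height: float
    crown_base_height: float
    crown_width_ew: float
    crown_width_ns: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "species", Species.parse(self.species))
        _require_positive("dbh", self.dbh)
        _require_positive("height", self.height)
        if self.crown_base_height < 0:
            raise ValueError(
                f"crown_base_height must be >= 0, got {self.crown_base_height}"
            )
        if self.height <= self.crown_base_height:
            raise ValueError(
                f"tree {self.tree_id}: height ({self.height} m) must exceed "
                f"crown base height ({self.crown_base_height} m)"
            )
        _require_positive("crown_width_ew", self.crown_width_ew)
        _require_positive("crown_width_ns", self.crown_width_ns)

    @property
    def dbh_m(self) -> float:
        """Stem diameter in metres."""
        return self.dbh / 100.0

    @property
    def crown_length(self) -> float:
        return self.height - self.crown_base_height


@dataclass(frozen=True)
class RootPlateGeometry:
    """Half-ellipsoid root-plate geometry.

    ``depth`` is the vertical semi-axis; ``length`` and ``width`` are the two
    full horizontal axes.  If a directly measured plate volume is supplied it
    overrides the geometric formula.
    """

    depth: float
    length: float
    width: float
    measured_volume: Optional[float] = None

    def __post_init__(self) -> None:
        _require_positive("depth", self.depth)
        _require_positive("length", self.length)
        _require_positive("width", self.width)
        if self.measured_volume is not None:
            _require_positive("measured_volume", self.measured_volume)


@dataclass(frozen=True)
class RootPlateMass:
    """Mass budget of one root plate (kg); build via :func:`root_plate_mass`."""

    coarse_root_mass: float
    soil_mass: float
    total: float
    coarse_root_fraction: float  # percent of total


@dataclass(frozen=True)
class SpeciesParams:
    """Per-species model constants.

    ``stem_coefficient`` scales the cubic stem-stiffness law; the anchorage
    fraction is the share of total root anchorage attributed to plate weight.
    The three ``allometric_*`` coefficients define the coarse-root biomass
    power law ``b0 * D**b1 * H**b2`` evaluated under ``allometric_convention``.
    """

    stem_coefficient: float
    anchorage_fraction: float
    allometric_b0: float
    allometric_b1: float
    allometric_b2: float
    allometric_convention: AllometricConvention

    def __post_init__(self) -> None:
        _require_positive("stem_coefficient", self.stem_coefficient)
        if not 0 < self.anchorage_fraction <= 1:
            raise ValueError(
                f"anchorage_fraction must be in (0, 1], got {self.anchorage_fraction}"
            )
        object.__setattr__(
            self,
            "allometric_convention",
            AllometricConvention(self.allometric_convention),
        )


#: Default per-species constants.  The allometric unit conventions were
#: calibrated against the reference root-plate mass table and are the only
#: combination that reproduces its coarse-root column within a few percent
#: for both species.
DEFAULT_SPECIES_PARAMS: dict[Species, SpeciesParams] = {
    Species.SPRUCE: SpeciesParams(
        stem_coefficient=3.315,
        anchorage_fraction=0.20,
        allometric_b0=4.3020,
        allometric_b1=2.9132,
        allometric_b2=-0.3292,
        allometric_convention=AllometricConvention.DBH_DM_OUT_KG,
    ),
    Species.KOREAN_PINE: SpeciesParams(
        stem_coefficient=3.589,
        anchorage_fraction=0.30,
        allometric_b0=4.7202,
        allometric_b1=2.7794,
        allometric_b2=-0.0536,
        allometric_convention=AllometricConvention.DBH_CM_OUT_G,
    ),
}


def species_defaults(species: "Species | str") -> SpeciesParams:
    """Return the default :class:`SpeciesParams` for *species*."""
    return DEFAULT_SPECIES_PARAMS[Species.parse(species)]


@dataclass(frozen=True)
class WindParams:
    """Wind-field constants entering the drag load.

    These rescale every overturning moment by the same factor ``mu`` and
    therefore affect ``R_m`` but never ``delta_prime`` or the hazard class.
    """

    air_density: float = 1.226  # kg·m⁻³
    drag_coefficient: float = 0.29
    wind_speed: float = 10.0  # m·s⁻¹

    def __post_init__(self) -> None:
        _require_positive("air_density", self.air_density)
        _require_positive("drag_coefficient", self.drag_coefficient)
        _require_positive("wind_speed", self.wind_speed)

    @property
    def mu(self) -> float:
        """Wind constant ``rho_a * C_d * v**2 / 6``."""
        return self.air_density * self.drag_coefficient * self.wind_speed**2 / 6.0


DEFAULT_WIND = WindParams()

#: Effective plate-soil bulk density, kg·m⁻³ — thickness-weighted mean of the
#: four reference soil layers (1.02, 0.92, 1.17, 1.24 g·cm⁻³ over equal
#: 15 cm layers).  Matches the reference table's soil-mass / volume ratios.
DEFAULT_SOIL_BULK_DENSITY = 1087.5


@dataclass(frozen=True)
class SoilLayer:
    depth_top: float  # cm
    depth_bottom: float  # cm
    bulk_density: float  # g·cm⁻³
    porosity: Optional[float] = None  # %
    water_content: Optional[float] = None  # %
    sand: Optional[float] = None  # %
    silt: Optional[float] = None  # %
    clay: Optional[float] = None  # %

    def __post_init__(self) -> None:
        if self.depth_bottom <= self.depth_top:
            raise ValueError("layer depth_bottom must exceed depth_top")
        _require_positive("bulk_density", self.bulk_density)

    @property
    def thickness(self) -> float:
        return self.depth_bottom - self.depth_top


@dataclass(frozen=True)
class SoilProfile:
    """Ordered, non-overlapping soil layers plus the effective bulk density
    (kg·m⁻³) used when converting plate volume to soil mass."""

    layers: tuple[SoilLayer, ...]
    effective_bulk_density: float

    def __post_init__(self) -> None:
        layers = tuple(self.layers)
        object.__setattr__(self, "layers", layers)
        for upper, lower in zip(layers, layers[1:]):
            if lower.depth_top < upper.depth_bottom:
                raise ValueError("soil layers must be ordered and non-overlapping")
        _require_positive("effective_bulk_density", self.effective_bulk_density)

    @classmethod
    def from_layers(
        cls, layers: Sequence[SoilLayer], plate_depth_m: Optional[float] = None
    ) -> "SoilProfile":
        """Build a profile whose effective density is the thickness-weighted
        mean bulk density over the layers intersecting ``plate_depth_m``
        (whole profile if omitted).  Density is converted g·cm⁻³ → kg·m⁻³."""
        layers = tuple(layers)
        if not layers:
            raise ValueError("at least one soil layer is required")
        limit_cm = math.inf if plate_depth_m is None else plate_depth_m * 100.0
        weighted = 0.0
        thickness = 0.0
        for layer in layers:
            overlap = max(0.0, min(layer.depth_bottom, limit_cm) - layer.depth_top)
            weighted += overlap * layer.bulk_density
            thickness += overlap
        if thickness <= 0:
            raise ValueError("plate depth does not intersect any soil layer")
        return cls(layers=layers, effective_bulk_density=weighted / thickness * 1000.0)


@dataclass(frozen=True)
class MomentBreakdown:
    """Every intermediate of the moment balance for one tree."""

    tree_id: str
    frontal_area: float  # m²
    wind_load: float  # N
    lever_arm: float  # m
    overturning_moment: float  # N·m
    stem_moment: float  # model units
    root_moment: float  # N·m
    root_lever_arm: float  # m
    resistance_coefficient: float
    delta_prime: float
    gravity: float = GRAVITY


# ---------------------------------------------------------------------------
# crown / wind


def crown_radius(tree: TreeMorphology) -> float:
    """Crown radius: mean of the two cardinal crown widths, halved."""
    return (tree.crown_width_ew + tree.crown_width_ns) / 4.0


def crown_frontal_area(tree: TreeMorphology) -> float:
    """Frontal area of the conical crown, ``R * (H - H0)`` (m²)."""
    if tree.height <= tree.crown_base_height:
        raise ValueError("tree height must exceed crown base height")
    return crown_radius(tree) * tree.crown_length


def wind_load(tree: TreeMorphology, wind: WindParams = DEFAULT_WIND) -> float:
    """Horizontal drag force on the crown, ``0.5 ρ C_d S v²`` (N)."""
    return 0.5 * wind.air_density * wind.drag_coefficient * crown_frontal_area(
        tree
    ) * wind.wind_speed**2


def wind_lever_arm(tree: TreeMorphology) -> float:
    """Height of the wind-load centroid: ``(H + 2 H0) / 3``, i.e. one third
    of the crown length above the crown base."""
    return (tree.height + 2.0 * tree.crown_base_height) / 3.0


def overturning_moment(tree: TreeMorphology, wind: WindParams = DEFAULT_WIND) -> float:
    """Overturning moment about the stem base, ``W_c * L`` (N·m)."""
    return wind_load(tree, wind) * wind_lever_arm(tree)


# ---------------------------------------------------------------------------
# stem


def stem_resistive_moment(tree: TreeMorphology, params: SpeciesParams) -> float:
    """Stem stiffness term ``a * D³ * H`` with D the stem diameter in metres."""
    return params.stem_coefficient * tree.dbh_m**3 * tree.height


# ---------------------------------------------------------------------------
# root plate


def root_plate_volume(geom: RootPlateGeometry) -> float:
    """Half-ellipsoid plate volume (m³): ``(π/6) * depth * length * width``
    with the depth a semi-axis and length/width full axes, so axes
    ``(r, 2r, 2r)`` recover the half-sphere ``(2/3) π r³``.  A supplied
    measured volume takes precedence."""
    if geom.measured_volume is not None:
        return geom.measured_volume
    return math.pi / 6.0 * geom.depth * geom.length * geom.width


def soil_mass_in_plate(volume: float, soil: "SoilProfile | float") -> float:
    """Soil mass enclosed in the plate, ``ρ_s * V_r`` (kg).

    ``soil`` may be a :class:`SoilProfile` or a bare effective bulk density
    in kg·m⁻³.
    """
    if volume < 0:
        raise ValueError("volume must be >= 0")
    density = soil.effective_bulk_density if isinstance(soil, SoilProfile) else soil
    if density is None:
        raise ValueError("effective bulk density is required")
    _require_positive("effective_bulk_density", density)
    return density * volume


def coarse_root_biomass(tree: TreeMorphology, params: SpeciesParams) -> float:
    """Coarse-root biomass ``b0 * D**b1 * H**b2`` in kg.

    The diameter unit and the output scale are fixed by the parameter set's
    :class:`AllometricConvention`; height is in metres throughout.
    """
    convention = params.allometric_convention
    if convention is AllometricConvention.DBH_DM_OUT_KG:
        diameter, scale = tree.dbh / 10.0, 1.0
    elif convention is AllometricConvention.DBH_CM_OUT_G:
        diameter, scale = tree.dbh, 1e-3
    else:  # pragma: no cover - enum is closed
        raise ValueError(f"unknown allometric convention: {convention!r}")
    return (
        params.allometric_b0
        * diameter**params.allometric_b1
        * tree.height**params.allometric_b2
        * scale
    )


def root_plate_mass(coarse_root_mass: float, soil_mass: float) -> RootPlateMass:
    """Combine the two mass components into a :class:`RootPlateMass`."""
    if coarse_root_mass < 0 or soil_mass < 0:
        raise ValueError("mass components must be >= 0")
    total = coarse_root_mass + soil_mass
    if total == 0:
        raise ValueError("root plate mass must be positive")
    return RootPlateMass(
        coarse_root_mass=coarse_root_mass,
        soil_mass=soil_mass,
        total=total,
        coarse_root_fraction=100.0 * coarse_root_mass / total,
    )


def root_plate_lever_arm(geom: RootPlateGeometry) -> float:
    """Lever arm of the plate's centre of gravity, ``4 * depth / (3π)`` (m)."""
    return 4.0 * geom.depth / (3.0 * math.pi)


def root_plate_resistive_moment(
    geom: RootPlateGeometry,
    mass: RootPlateMass,
    params: SpeciesParams,
    gravity: float = GRAVITY,
) -> float:
    """Restoring moment of plate weight, ``f_r * L_r * G * g`` (N·m)."""
    return params.anchorage_fraction * root_plate_lever_arm(geom) * mass.total * gravity


# ---------------------------------------------------------------------------
# indices


def resistance_coefficient(
    stem_moment: float, root_moment: float, overturning: float
) -> float:
    """``R_m = (M_s + M_r) / M_w``; requires a positive overturning moment."""
    if overturning <= 0:
        raise ValueError("overturning moment must be positive")
    return (stem_moment + root_moment) / overturning


def delta_prime(
    tree: TreeMorphology,
    geom: RootPlateGeometry,
    mass: RootPlateMass,
    params: SpeciesParams,
    gravity: float = GRAVITY,
) -> float:
    """Wind-independent uprooting-resistance index.

    ``Δ' = [3π a D³ H + 4 f_r D_rp G g] / [3π R (H + 2 H0) (H − H0)]`` —
    exactly ``mu * R_m`` for any wind constant ``mu > 0``.
    """
    radius = crown_radius(tree)
    if radius <= 0:
        raise ValueError("crown radius must be positive")
    numerator = (
        3.0 * math.pi * params.stem_coefficient * tree.dbh_m**3 * tree.height
        + 4.0 * params.anchorage_fraction * geom.depth * mass.total * gravity
    )
    denominator = (
        3.0
        * math.pi
        * radius
        * (tree.height + 2.0 * tree.crown_base_height)
        * tree.crown_length
    )
    return numerator / denominator


def assess_tree(
    tree: TreeMorphology,
    geom: RootPlateGeometry,
    soil: "SoilProfile | float" = DEFAULT_SOIL_BULK_DENSITY,
    params: Optional[SpeciesParams] = None,
    wind: WindParams = DEFAULT_WIND,
) -> MomentBreakdown:
    """Run the full moment balance for one tree.

    Returns a :class:`MomentBreakdown` with every intermediate quantity;
    ``delta_prime`` is computed from the closed form and agrees with
    ``mu * resistance_coefficient`` to floating-point accuracy.
    """
    if params is None:
        params = species_defaults(tree.species)
    volume = root_plate_volume(geom)
    mass = root_plate_mass(
        coarse_root_biomass(tree, params), soil_mass_in_plate(volume, soil)
    )
    m_w = overturning_moment(tree, wind)
    m_s = stem_resistive_moment(tree, params)
    m_r = root_plate_resistive_moment(geom, mass, params)
    return MomentBreakdown(
        tree_id=tree.tree_id,
        frontal_area=crown_frontal_area(tree),
        wind_load=wind_load(tree, wind),
        lever_arm=wind_lever_arm(tree),
        overturning_moment=m_w,
        stem_moment=m_s,
        root_moment=m_r,
        root_lever_arm=root_plate_lever_arm(geom),
        resistance_coefficient=resistance_coefficient(m_s, m_r, m_w),
        delta_prime=delta_prime(tree, geom, mass, params),
    )
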