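import math

import numpy as np
import pytest

from windfirm.core import (
    DEFAULT_SOIL_BULK_DENSITY,
    AllometricConvention,
    RootPlateGeometry,
    SoilLayer,
    SoilProfile,
    Species,
    SpeciesParams,
    TreeMorphology,
    WindParams,
    assess_tree,
    coarse_root_biomass,
    crown_frontal_area,
    crown_radius,
    delta_prime,
    overturning_moment,
    resistance_coefficient,
    root_plate_lever_arm,
    root_plate_mass,
    root_plate_resistive_moment,
    root_plate_volume,
    soil_mass_in_plate,
    species_defaults,
    stem_resistive_moment,
    wind_lever_arm,
    wind_load,
)

from conftest import simple_plate, simple_tree


class TestTreeMorphology:
    def test_rejects_height_below_crown_base(self):
        with pytest.raises(ValueError, match="must exceed crown base"):
            simple_tree(height=4.0, base=5.0)

    def test_rejects_nonpositive_widths(self):
        with pytest.raises(ValueError, match="crown_width"):
            simple_tree(width_ew=0.0)

    def test_rejects_nonpositive_dbh(self):
        with pytest.raises(ValueError, match="dbh"):
            simple_tree(dbh=-1.0)

    def test_species_normalized_from_string(self):
        tree = simple_tree(species="Korean Pine")
        assert tree.species is Species.KOREAN_PINE


class TestCrown:
    def test_crown_radius_s1(self, s1_tree):
        assert crown_radius(s1_tree) == pytest.approx(2.75)

    def test_crown_radius_symmetric(self):
        assert crown_radius(simple_tree(width_ew=2, width_ns=2)) == pytest.approx(1.0)

    def test_crown_radius_k3(self):
        tree = simple_tree(width_ew=8.6, width_ns=8.7)
        assert crown_radius(tree) == pytest.approx(4.325)

    def test_frontal_area_direct_product(self):
        tree = simple_tree(height=10, base=4, width_ew=4, width_ns=4)  # R = 2
        assert crown_frontal_area(tree) == pytest.approx(12.0)

    def test_frontal_area_s1(self, s1_tree):
        assert crown_frontal_area(s1_tree) == pytest.approx(11.275)

    def test_frontal_area_shrinks_with_crown(self):
        narrow = simple_tree(width_ew=1e-6, width_ns=1e-6)
        assert crown_frontal_area(narrow) < 1e-4


class TestWind:
    def test_unit_inputs(self):
        tree = simple_tree(height=2, base=1, width_ew=2, width_ns=2)
        wind = WindParams(air_density=1, drag_coefficient=1, wind_speed=1)
        assert wind_load(tree, wind) == pytest.approx(0.5)

    def test_speed_squared_scaling(self, s1_tree):
        base = wind_load(s1_tree, WindParams(wind_speed=5))
        assert wind_load(s1_tree, WindParams(wind_speed=10)) == pytest.approx(4 * base)

    def test_hand_evaluation(self, s1_tree):
        wind = WindParams(air_density=1.2, drag_coefficient=0.3, wind_speed=10)
        assert wind_load(s1_tree, wind) == pytest.approx(203.0, abs=0.1)

    def test_rejects_nonpositive_speed(self):
        with pytest.raises(ValueError, match="wind_speed"):
            WindParams(wind_speed=0)

    def test_lever_arm(self):
        assert wind_lever_arm(simple_tree(height=10, base=4)) == pytest.approx(6.0)

    def test_lever_arm_ground_level_crown(self):
        tree = simple_tree(height=9, base=0)
        assert wind_lever_arm(tree) == pytest.approx(3.0)

    def test_lever_arm_s1(self, s1_tree):
        assert wind_lever_arm(s1_tree) == pytest.approx((7.8 + 7.4) / 3)

    def test_overturning_is_load_times_lever(self):
        tree = simple_tree(height=2, base=1, width_ew=2, width_ns=2)
        wind = WindParams(air_density=1, drag_coefficient=1, wind_speed=1)
        assert overturning_moment(tree, wind) == pytest.approx(
            wind_load(tree, wind) * 4 / 3
        )

    def test_closed_form_with_unit_mu(self, s1_tree):
        # rho*Cd*v^2 = 6 makes mu exactly 1
        wind = WindParams(air_density=6, drag_coefficient=1, wind_speed=1)
        assert wind.mu == pytest.approx(1.0)
        expected = 2.75 * (7.8 + 2 * 3.7) * (7.8 - 3.7)
        assert overturning_moment(s1_tree, wind) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(171.38, abs=0.005)

    def test_product_vs_closed_form_randomized(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            tree = simple_tree(
                dbh=rng.uniform(5, 90),
                height=rng.uniform(6, 40),
                base=rng.uniform(0.5, 5),
                width_ew=rng.uniform(1, 15),
                width_ns=rng.uniform(1, 15),
            )
            wind = WindParams(
                air_density=rng.uniform(0.9, 1.4),
                drag_coefficient=rng.uniform(0.1, 1.0),
                wind_speed=rng.uniform(1, 40),
            )
            closed = (
                wind.mu
                * crown_radius(tree)
                * (tree.height + 2 * tree.crown_base_height)
                * tree.crown_length
            )
            assert overturning_moment(tree, wind) == pytest.approx(closed, rel=1e-9)


class TestStemMoment:
    def test_unit_case(self, spruce_params):
        tree = simple_tree(dbh=100, height=1.0, base=0.2)
        assert stem_resistive_moment(tree, spruce_params) == pytest.approx(3.315)

    def test_cubic_in_diameter(self, spruce_params):
        small = simple_tree(dbh=20)
        large = simple_tree(dbh=40)
        ratio = stem_resistive_moment(large, spruce_params) / stem_resistive_moment(
            small, spruce_params
        )
        assert ratio == pytest.approx(8.0)

    def test_s1_value(self, s1_tree, spruce_params):
        assert stem_resistive_moment(s1_tree, spruce_params) == pytest.approx(
            0.4922, abs=2e-4
        )


class TestRootPlate:
    def test_half_sphere_limit(self):
        geom = RootPlateGeometry(depth=1.0, length=2.0, width=2.0)
        assert root_plate_volume(geom) == pytest.approx(2 * math.pi / 3, abs=1e-12)

    def test_unit_box(self):
        geom = RootPlateGeometry(depth=1, length=1, width=1)
        assert root_plate_volume(geom) == pytest.approx(math.pi / 6)

    def test_measured_volume_override(self):
        geom = simple_plate(volume=0.28)
        assert root_plate_volume(geom) == 0.28

    def test_rejects_nonpositive_dimension(self):
        with pytest.raises(ValueError):
            RootPlateGeometry(depth=0, length=1, width=1)

    def test_soil_mass_linear(self):
        assert soil_mass_in_plate(2.0, 1100.0) == pytest.approx(2200.0)
        assert soil_mass_in_plate(0.0, 1100.0) == 0.0

    def test_soil_mass_matches_reference_row(self):
        assert soil_mass_in_plate(2.00, 1087.7) == pytest.approx(2175.40)

    def test_soil_mass_requires_density(self):
        with pytest.raises(ValueError):
            soil_mass_in_plate(1.0, None)

    def test_mass_budget_s1(self):
        mass = root_plate_mass(40.01, 310.29)
        assert mass.total == pytest.approx(350.30)
        assert mass.coarse_root_fraction == pytest.approx(11.42, abs=0.005)

    def test_mass_budget_zero_coarse(self):
        mass = root_plate_mass(0.0, 100.0)
        assert mass.total == 100.0
        assert mass.coarse_root_fraction == 0.0

    def test_mass_budget_s19(self):
        mass = root_plate_mass(17.57, 302.04)
        assert 319.61 <= mass.total <= 319.62
        assert round(mass.coarse_root_fraction, 2) == pytest.approx(5.50)

    def test_mass_rejects_negative(self):
        with pytest.raises(ValueError):
            root_plate_mass(-1.0, 10.0)

    def test_resistive_moment_engineered_lever(self, spruce_params):
        geom = simple_plate(depth=3 * math.pi / 4)
        assert root_plate_lever_arm(geom) == pytest.approx(1.0)
        mass = root_plate_mass(50.0, 50.0)
        assert root_plate_resistive_moment(geom, mass, spruce_params) == pytest.approx(
            0.2 * 100 * 9.81
        )

    def test_resistive_moment_k1_hand_value(self, pine_params):
        geom = simple_plate(depth=0.5)
        mass = root_plate_mass(32.96, 535.31 - 32.96)
        assert root_plate_resistive_moment(geom, mass, pine_params) == pytest.approx(
            334.3, abs=0.1
        )

    def test_resistive_moment_linear_in_mass_and_depth(self, spruce_params):
        geom = simple_plate(depth=0.4)
        m1 = root_plate_resistive_moment(geom, root_plate_mass(10, 90), spruce_params)
        m2 = root_plate_resistive_moment(geom, root_plate_mass(20, 180), spruce_params)
        assert m2 == pytest.approx(2 * m1)
        deeper = simple_plate(depth=0.8)
        assert root_plate_resistive_moment(
            deeper, root_plate_mass(10, 90), spruce_params
        ) == pytest.approx(2 * m1)

    def test_anchorage_fraction_zero_rejected(self):
        with pytest.raises(ValueError, match="anchorage_fraction"):
            SpeciesParams(
                stem_coefficient=1.0,
                anchorage_fraction=0.0,
                allometric_b0=1,
                allometric_b1=1,
                allometric_b2=0,
                allometric_convention=AllometricConvention.DBH_DM_OUT_KG,
            )


class TestAllometry:
    def test_spruce_s1(self, s1_tree, spruce_params):
        assert coarse_root_biomass(s1_tree, spruce_params) == pytest.approx(
            40.01, rel=0.05
        )

    def test_korean_pine_k6(self, pine_params):
        tree = simple_tree(
            dbh=91.7, height=30.9, base=18.3, species=Species.KOREAN_PINE
        )
        assert coarse_root_biomass(tree, pine_params) == pytest.approx(1149.48, rel=0.05)

    def test_constant_when_exponents_zero(self):
        params = SpeciesParams(
            stem_coefficient=1.0,
            anchorage_fraction=0.5,
            allometric_b0=7.5,
            allometric_b1=0.0,
            allometric_b2=0.0,
            allometric_convention=AllometricConvention.DBH_DM_OUT_KG,
        )
        assert coarse_root_biomass(simple_tree(dbh=12), params) == 7.5
        assert coarse_root_biomass(simple_tree(dbh=77), params) == 7.5

    def test_increasing_in_diameter(self, spruce_params):
        values = [
            coarse_root_biomass(simple_tree(dbh=d), spruce_params)
            for d in (10, 20, 40, 80)
        ]
        assert values == sorted(values)
        assert len(set(values)) == 4

    def test_unknown_convention_rejected(self):
        with pytest.raises(ValueError):
            SpeciesParams(
                stem_coefficient=1.0,
                anchorage_fraction=0.5,
                allometric_b0=1,
                allometric_b1=1,
                allometric_b2=0,
                allometric_convention="dbh_furlongs",
            )


class TestIndices:
    def test_resistance_coefficient_basic(self):
        assert resistance_coefficient(1, 1, 1) == pytest.approx(2.0)
        assert resistance_coefficient(0, 0, 5) == 0.0
        assert resistance_coefficient(4.64, 1100, 1615) == pytest.approx(
            0.6840, abs=1e-3
        )

    def test_resistance_coefficient_rejects_nonpositive_mw(self):
        with pytest.raises(ValueError):
            resistance_coefficient(1, 1, 0)

    def test_delta_prime_unity_by_construction(self, s1_tree, spruce_params):
        geom = simple_plate(depth=0.5)
        tree = s1_tree
        denominator = (
            3
            * math.pi
            * crown_radius(tree)
            * (tree.height + 2 * tree.crown_base_height)
            * tree.crown_length
        )
        stem_term = (
            3 * math.pi * spruce_params.stem_coefficient * tree.dbh_m**3 * tree.height
        )
        total = (denominator - stem_term) / (
            4 * spruce_params.anchorage_fraction * geom.depth * 9.81
        )
        mass = root_plate_mass(0.0, total)
        assert delta_prime(tree, geom, mass, spruce_params) == pytest.approx(
            1.0, rel=1e-12
        )

    def test_delta_equals_mu_times_rm_randomized(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            tree = simple_tree(
                dbh=rng.uniform(5, 90),
                height=rng.uniform(6, 40),
                base=rng.uniform(0.5, 5),
                width_ew=rng.uniform(1, 15),
                width_ns=rng.uniform(1, 15),
                species=list(Species)[int(rng.integers(0, 2))],
            )
            geom = simple_plate(
                depth=rng.uniform(0.2, 1.0),
                length=rng.uniform(0.5, 4),
                width=rng.uniform(0.5, 4),
            )
            for _ in range(5):
                wind = WindParams(
                    air_density=rng.uniform(0.9, 1.4),
                    drag_coefficient=rng.uniform(0.1, 1.0),
                    wind_speed=rng.uniform(1, 40),
                )
                breakdown = assess_tree(tree, geom, wind=wind)
                assert breakdown.delta_prime == pytest.approx(
                    wind.mu * breakdown.resistance_coefficient, rel=1e-9
                )

    def test_delta_increasing_in_diameter(self, spruce_params):
        geom = simple_plate()
        deltas = []
        for dbh in (10, 20, 30, 40, 50):
            tree = simple_tree(dbh=dbh)
            breakdown = assess_tree(tree, geom, params=spruce_params)
            deltas.append(breakdown.delta_prime)
        assert deltas == sorted(deltas)
        assert len(set(deltas)) == 5


class TestSoilProfile:
    def _layers(self):
        return [
            SoilLayer(0, 15, 1.02),
            SoilLayer(15, 30, 0.92),
            SoilLayer(30, 45, 1.17),
            SoilLayer(45, 60, 1.24),
        ]

    def test_thickness_weighted_mean(self):
        profile = SoilProfile.from_layers(self._layers())
        assert profile.effective_bulk_density == pytest.approx(1087.5)
        assert profile.effective_bulk_density == pytest.approx(
            DEFAULT_SOIL_BULK_DENSITY
        )

    def test_plate_depth_limits_layers(self):
        profile = SoilProfile.from_layers(self._layers(), plate_depth_m=0.30)
        assert profile.effective_bulk_density == pytest.approx(970.0)

    def test_overlapping_layers_rejected(self):
        with pytest.raises(ValueError, match="non-overlapping"):
            SoilProfile(
                layers=(SoilLayer(0, 20, 1.0), SoilLayer(10, 30, 1.1)),
                effective_bulk_density=1000.0,
            )


class TestAssessTree:
    def test_breakdown_internally_consistent(self, s1_tree):
        breakdown = assess_tree(s1_tree, simple_plate(volume=0.28))
        assert breakdown.overturning_moment == pytest.approx(
            breakdown.wind_load * breakdown.lever_arm, rel=1e-12
        )
        assert breakdown.resistance_coefficient == pytest.approx(
            (breakdown.stem_moment + breakdown.root_moment)
            / breakdown.overturning_moment,
            rel=1e-12,
        )
        assert breakdown.delta_prime > 0

    def test_uses_species_defaults(self, s1_tree):
        explicit = assess_tree(
            s1_tree, simple_plate(), params=species_defaults(Species.SPRUCE)
        )
        implicit = assess_tree(s1_tree, simple_plate())
        assert explicit == implicit
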