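import pytest

from windfirm import fixtures
from windfirm.core import (
    RootPlateGeometry,
    Species,
    TreeMorphology,
    species_defaults,
)


@pytest.fixture(scope="session")
def table2():
    return fixtures.load_rootplate_table()


@pytest.fixture(scope="session")
def table4():
    return fixtures.load_delta_labels()


@pytest.fixture(scope="session")
def table5():
    return fixtures.load_morphology_table()


@pytest.fixture
def s1_tree():
    """First spruce sample of the morphology table."""
    return TreeMorphology(
        tree_id="S1",
        species=Species.SPRUCE,
        dbh=26.7,
        height=7.8,
        crown_base_height=3.7,
        crown_width_ew=5.2,
        crown_width_ns=5.8,
    )


@pytest.fixture
def spruce_params():
    return species_defaults(Species.SPRUCE)


@pytest.fixture
def pine_params():
    return species_defaults(Species.KOREAN_PINE)


def tree_from_row(row) -> TreeMorphology:
    return TreeMorphology(
        tree_id=row["tree_id"],
        species=Species.parse(row["species"]),
        dbh=float(row["dbh_cm"]),
        height=float(row["height_m"]),
        crown_base_height=float(row["crown_base_m"]),
        crown_width_ew=float(row["crown_ew_m"]),
        crown_width_ns=float(row["crown_ns_m"]),
    )


def simple_tree(
    dbh=30.0,
    height=10.0,
    base=4.0,
    width_ew=2.0,
    width_ns=2.0,
    species=Species.SPRUCE,
    tree_id="T",
) -> TreeMorphology:
    return TreeMorphology(
        tree_id=tree_id,
        species=species,
        dbh=dbh,
        height=height,
        crown_base_height=base,
        crown_width_ew=width_ew,
        crown_width_ns=width_ns,
    )


def simple_plate(depth=0.5, length=2.0, width=2.0, volume=None) -> RootPlateGeometry:
    return RootPlateGeometry(
        depth=depth, length=length, width=width, measured_volume=volume
    )
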