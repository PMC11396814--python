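"""Packaged reference tables.

The five CSV resources mirror the published tables cell for cell, anomalies
included.  Known inconsistencies are never corrected in the data; they are
surfaced through per-row ``flag`` columns and the :data:`ANOMALIES` notes.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd

__all__ = [
    "ANOMALIES",
    "TABLE_FILES",
    "load_soil_table",
    "load_rootplate_table",
    "load_uprooted_reference_table",
    "load_delta_labels",
    "load_morphology_table",
    "export_fixtures",
]

TABLE_FILES = {
    "table1_soil": "table1_soil.csv",
    "table2_rootplates": "table2_rootplates.csv",
    "table3_uprooted_reference": "table3_uprooted_reference.csv",
    "table4_delta_labels": "table4_delta_labels.csv",
    "table5_morphology": "table5_morphology.csv",
}

#: Documented inconsistencies carried verbatim from the source tables.
ANOMALIES = {
    "S3_label": (
        "Sample S3 has index 5.32 but is labelled High; the banding rule "
        "puts it at Low. Shipped verbatim with flag 'label_anomaly'."
    ),
    "table3_columns": (
        "The Korean pine reference row pairs a 10.02 m3 plate with only "
        "1624.99 kg of mass; volume and mass columns look swapped or "
        "mislabelled. Flagged 'volume_mass_suspect', not reconciled."
    ),
    "table2_range": (
        "The stated plate-mass range maximum (5650.87 kg) conflicts with "
        "the table maximum 5705.68 kg (K6). The table values are shipped."
    ),
    "table1_porosity": (
        "Printed porosity values are inconsistent with "
        "100*(1 - bulk/2.65); shipped as data only."
    ),
}


def _read(name: str) -> pd.DataFrame:
    with resources.files("windfirm.data").joinpath(TABLE_FILES[name]).open(
        "r", encoding="utf-8"
    ) as handle:
        return pd.read_csv(handle)


def load_soil_table() -> pd.DataFrame:
    """Soil physical properties per depth layer (mean and SE columns)."""
    return _read("table1_soil")


def load_rootplate_table() -> pd.DataFrame:
    """Per-sample root-plate volume and mass budget (40 rows)."""
    return _read("table2_rootplates")


def load_uprooted_reference_table() -> pd.DataFrame:
    """Mean morphology of the uprooted reference trees (one row per species)."""
    return _read("table3_uprooted_reference")


def load_delta_labels() -> pd.DataFrame:
    """Published per-sample resistance index and hazard label (40 rows)."""
    return _read("table4_delta_labels")


def load_morphology_table() -> pd.DataFrame:
    """Above-ground morphology of the 40 standing samples."""
    return _read("table5_morphology")


def export_fixtures(directory: "str | Path") -> list[Path]:
    """Write every packaged table into *directory*; returns the paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []
    for filename in TABLE_FILES.values():
        text = (
            resources.files("windfirm.data").joinpath(filename).read_text("utf-8")
        )
        target = directory / filename
        target.write_text(text, encoding="utf-8")
        written.append(target)
    return written
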