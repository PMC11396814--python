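"""CSV and TOML input/output plus the end-to-end assessment pipeline.

CSV dialect is fixed: UTF-8, comma separator, '.' decimal, header row.
Validation errors always name the offending row and field; a whole file is
validated before the first error list is raised so users see every problem
at once.
"""

from __future__ import annotations

import math
import sys
import tomllib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .core import (
    DEFAULT_SOIL_BULK_DENSITY,
    DEFAULT_WIND,
    RootPlateGeometry,
    SoilLayer,
    SoilProfile,
    Species,
    SpeciesParams,
    TreeMorphology,
    WindParams,
    assess_tree,
    species_defaults,
)
from .field import GPRScanRecord
from .hazard import (
    HazardThresholds,
    UprootedReference,
    classify_tree,
    critical_thresholds,
    summarize_stand,
)

__all__ = [
    "SchemaError",
    "AssessmentError",
    "RunConfig",
    "read_tree_table",
    "read_rootplate_table",
    "read_scan_table",
    "read_reference_values",
    "read_thresholds",
    "write_thresholds",
    "run_assessment",
    "write_report",
]

TREE_COLUMNS = [
    "tree_id",
    "species",
    "dbh_cm",
    "height_m",
    "crown_base_m",
    "crown_ew_m",
    "crown_ns_m",
]
ROOTPLATE_COLUMNS = ["tree_id", "depth_m", "length_m", "width_m"]
SCAN_COLUMNS = [
    "tree_id",
    "species",
    "transect_radius_m",
    "depth_bin",
    "scan_length_m",
    "short_axis_m",
    "root_count",
]


class SchemaError(ValueError):
    """A tabular input failed validation; message lists every bad row."""


class AssessmentError(ValueError):
    """One or more trees could not be assessed."""


def _load_csv(path: "str | Path", required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    frame = pd.read_csv(path, encoding="utf-8")
    missing = [column for column in required if column not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {', '.join(missing)}")
    return frame


def _collect(path, frame, builder) -> list:
    records, errors = [], []
    for index, row in frame.iterrows():
        try:
            records.append(builder(row))
        except (ValueError, TypeError) as exc:
            errors.append(f"row {index + 2}: {exc}")  # +2: header + 1-based
    if errors:
        raise SchemaError(f"{path}: " + "; ".join(errors))
    return records


def read_tree_table(path: "str | Path") -> list[TreeMorphology]:
    """Read a standing-tree morphology CSV into validated records."""
    frame = _load_csv(path, TREE_COLUMNS)

    def build(row) -> TreeMorphology:
        return TreeMorphology(
            tree_id=str(row["tree_id"]),
            species=Species.parse(row["species"]),
            dbh=float(row["dbh_cm"]),
            height=float(row["height_m"]),
            crown_base_height=float(row["crown_base_m"]),
            crown_width_ew=float(row["crown_ew_m"]),
            crown_width_ns=float(row["crown_ns_m"]),
        )

    return _collect(path, frame, build)


def read_rootplate_table(path: "str | Path") -> dict[str, RootPlateGeometry]:
    """Read root-plate geometry keyed by tree id; ``volume_m3`` is optional
    and, when present and non-empty, overrides the geometric volume."""
    frame = _load_csv(path, ROOTPLATE_COLUMNS)

    def build(row) -> tuple[str, RootPlateGeometry]:
        volume = None
        if "volume_m3" in row.index and not pd.isna(row["volume_m3"]):
            volume = float(row["volume_m3"])
        return str(row["tree_id"]), RootPlateGeometry(
            depth=float(row["depth_m"]),
            length=float(row["length_m"]),
            width=float(row["width_m"]),
            measured_volume=volume,
        )

    return dict(_collect(path, frame, build))


def read_scan_table(path: "str | Path") -> list[GPRScanRecord]:
    """Read a radar scan CSV into validated :class:`GPRScanRecord` rows."""
    frame = _load_csv(path, SCAN_COLUMNS)

    def build(row) -> GPRScanRecord:
        return GPRScanRecord(
            tree_id=str(row["tree_id"]),
            species=Species.parse(row["species"]),
            transect_radius=float(row["transect_radius_m"]),
            depth_bin=row["depth_bin"],
            scan_length=float(row["scan_length_m"]),
            short_axis=float(row["short_axis_m"]),
            root_count=int(row["root_count"]),
        )

    return _collect(path, frame, build)


def read_reference_values(path: "str | Path") -> dict[Species, UprootedReference]:
    """Read per-tree reference index values (columns species, delta_u)."""
    frame = _load_csv(path, ["species", "delta_u"])
    references = {}
    for species, sub in frame.groupby("species"):
        parsed = Species.parse(species)
        references[parsed] = UprootedReference(
            species=parsed,
            values=tuple(float(v) for v in sub["delta_u"]),
            source=str(path),
        )
    return references


def read_thresholds(path: "str | Path") -> dict[Species, HazardThresholds]:
    """Read per-species thresholds from TOML ([species] tables with t95/t99)."""
    with open(path, "rb") as handle:
        data = tomllib.load(handle)
    thresholds = {}
    for key, block in data.items():
        thresholds[Species.parse(key)] = HazardThresholds(
            t95=float(block["t95"]),
            t99=float(block["t99"]),
            rounding=int(block.get("rounding", 2)),
        )
    if not thresholds:
        raise SchemaError(f"{path}: no species threshold tables found")
    return thresholds


def write_thresholds(
    thresholds: Mapping[Species, HazardThresholds], path: "str | Path"
) -> None:
    lines = []
    for species, value in thresholds.items():
        lines += [
            f"[{Species.parse(species).value}]",
            f"t95 = {value.t95}",
            f"t99 = {value.t99}",
            f"rounding = {value.rounding}",
            "",
        ]
    Path(path).write_text("\n".join(lines), encoding="utf-8")


@dataclass(frozen=True)
class RunConfig:
    """Validated run parameters; defaults reproduce the published settings."""

    species_params: dict[Species, SpeciesParams] = field(
        default_factory=lambda: {sp: species_defaults(sp) for sp in Species}
    )
    wind: WindParams = DEFAULT_WIND
    soil_bulk_density: float = DEFAULT_SOIL_BULK_DENSITY
    thresholds: Optional[dict[Species, HazardThresholds]] = None
    rounding: int = 2
    seed: int = 0

    @classmethod
    def from_toml(cls, path: "str | Path") -> "RunConfig":
        with open(path, "rb") as handle:
            data = tomllib.load(handle)
        kwargs: dict = {}
        if "wind" in data:
            kwargs["wind"] = WindParams(**data["wind"])
        if "soil" in data:
            kwargs["soil_bulk_density"] = float(data["soil"]["bulk_density_kg_m3"])
        if "species" in data:
            params = {sp: species_defaults(sp) for sp in Species}
            for key, block in data["species"].items():
                params[Species.parse(key)] = SpeciesParams(**block)
            kwargs["species_params"] = params
        if "thresholds" in data:
            kwargs["thresholds"] = {
                Species.parse(key): HazardThresholds(
                    t95=float(block["t95"]),
                    t99=float(block["t99"]),
                    rounding=int(block.get("rounding", 2)),
                )
                for key, block in data["thresholds"].items()
            }
        if "rounding" in data:
            kwargs["rounding"] = int(data["rounding"])
        if "seed" in data:
            kwargs["seed"] = int(data["seed"])
        return cls(**kwargs)


def run_assessment(
    trees: Sequence[TreeMorphology],
    plates: Mapping[str, RootPlateGeometry],
    thresholds: Mapping[Species, HazardThresholds],
    soil: "SoilProfile | float" = DEFAULT_SOIL_BULK_DENSITY,
    species_params: Optional[Mapping[Species, SpeciesParams]] = None,
    wind: WindParams = DEFAULT_WIND,
    skip_invalid: bool = False,
) -> pd.DataFrame:
    """Full pipeline: moment balance plus hazard level for every tree.

    Unresolvable trees (missing plate or thresholds, failed invariants) are
    collected and reported together; the run aborts unless *skip_invalid*.
    Output is deterministic given identical inputs.
    """
    thresholds = {Species.parse(k): v for k, v in thresholds.items()}
    rows, problems = [], []
    for tree in trees:
        try:
            if tree.tree_id not in plates:
                raise AssessmentError("no root-plate record")
            if tree.species not in thresholds:
                raise AssessmentError(f"no thresholds for species {tree.species.value}")
            params = (
                species_params[tree.species]
                if species_params is not None
                else species_defaults(tree.species)
            )
            breakdown = assess_tree(
                tree, plates[tree.tree_id], soil=soil, params=params, wind=wind
            )
            level = classify_tree(breakdown.delta_prime, thresholds[tree.species])
            rows.append(
                {
                    "tree_id": tree.tree_id,
                    "species": tree.species.value,
                    "frontal_area_m2": breakdown.frontal_area,
                    "wind_load_n": breakdown.wind_load,
                    "lever_arm_m": breakdown.lever_arm,
                    "overturning_moment_nm": breakdown.overturning_moment,
                    "stem_moment": breakdown.stem_moment,
                    "root_moment_nm": breakdown.root_moment,
                    "resistance_coefficient": breakdown.resistance_coefficient,
                    "delta_prime": breakdown.delta_prime,
                    "hazard_level": level.value,
                }
            )
        except (ValueError, KeyError) as exc:
            problems.append(f"{tree.tree_id}: {exc}")
    if problems and not skip_invalid:
        raise AssessmentError(
            f"{len(problems)} tree(s) could not be assessed: " + "; ".join(problems)
        )
    return pd.DataFrame(rows)


def write_report(frame: pd.DataFrame, path: "str | Path") -> None:
    """Write a report CSV with values at 6 significant digits (round-trip
    stable at that precision)."""
    frame.to_csv(path, index=False, float_format="%.6g", encoding="utf-8")
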