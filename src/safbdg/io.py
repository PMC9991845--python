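"""Study tables, food-group mapping config, readers/writers and validation.

Three comma-delimited UTF-8 tables (header row mandatory) describe a study:

``participants``
    One row per subject: ``subject_id, pair_id, status, age, menopausal,
    er, pr, her2, ethnicity, income_band, education, smoker, waist_cm,
    height_cm, weight_kg, hiv, pa_metric, pa_active, alcohol_g``.
    ``status`` is ``case``/``control``; each ``pair_id`` must map to exactly
    one case and one control. Empty categorical cells become ``"unknown"``.

``intakes``
    One row per subject, one column per food item, values in g/d.

``nutrients``
    One row per subject: ``subject_id, energy_kj, fat_g, sfa_g,
    added_sugar_g, alcohol_g``.

The food-group mapping is a YAML config (see :func:`read_mapping`) assigning
every food item to at most one scored food family (fruit/veg, legumes,
liquid dairy, hard cheese, fish/chicken/lean meat, eggs, starchy) and to one
of the nine FAO dietary-diversity groups; starchy items carry the gram
weight of one food-guide unit.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .exceptions import (
    DomainError,
    MappingError,
    PairingError,
    SchemaError,
    UnmappedItemWarning,
)

logger = logging.getLogger(__name__)

PARTICIPANT_COLUMNS = [
    "subject_id", "pair_id", "status", "age", "menopausal", "er", "pr",
    "her2", "ethnicity", "income_band", "education", "smoker", "waist_cm",
    "height_cm", "weight_kg", "hiv", "pa_metric", "pa_active", "alcohol_g",
]
CATEGORICAL_COLUMNS = [
    "menopausal", "er", "pr", "her2", "ethnicity", "income_band",
    "education", "hiv",
]
NUTRIENT_COLUMNS = [
    "subject_id", "energy_kj", "fat_g", "sfa_g", "added_sugar_g", "alcohol_g",
]

#: Scored food families; an item may belong to at most one of these.
FOOD_FAMILIES = (
    "fruit_veg", "legume", "dairy_liquid", "hard_cheese",
    "fish_chicken_leanmeat", "egg", "starchy",
)

OBESITY_BMI = 30.0


@dataclass
class GroupMapping:
    """Food-item to food-group assignment.

    ``table`` is indexed by food-item id with columns ``dds_group`` (1-9 FAO
    group code or NaN), ``family`` (one of :data:`FOOD_FAMILIES` or None),
    ``starchy_unit_g`` (grams per starchy food-guide unit, NaN unless
    starchy) and ``kj_per_g`` (toy energy density, optional).
    """

    table: pd.DataFrame
    schema_version: int = 1

    @property
    def items(self) -> list[str]:
        return list(self.table.index)

    def items_in_family(self, family: str) -> list[str]:
        return list(self.table.index[self.table["family"] == family])

    def items_in_dds_group(self, group: int) -> list[str]:
        return list(self.table.index[self.table["dds_group"] == group])

    def unmapped(self, item_ids) -> list[str]:
        return sorted(set(item_ids) - set(self.table.index))

    def check_coverage(self, item_ids) -> list[str]:
        """Warn about intake items absent from the mapping; return them."""
        missing = self.unmapped(item_ids)
        if missing:
            warnings.warn(
                f"{len(missing)} intake item(s) not covered by the mapping: "
                f"{', '.join(missing)}",
                UnmappedItemWarning,
                stacklevel=2,
            )
        return missing


@dataclass
class StudyTable:
    """Aligned participant, intake and nutrient tables for one study."""

    participants: pd.DataFrame
    intakes: pd.DataFrame
    nutrients: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    @property
    def subject_ids(self) -> pd.Index:
        return self.participants.index

    @property
    def n_subjects(self) -> int:
        return len(self.participants)

    @property
    def n_pairs(self) -> int:
        return self.participants["pair_id"].nunique()

    def validate(self) -> "StudyTable":
        validate_participants(self.participants)
        validate_nutrients(self.nutrients)
        for name, frame in (("intakes", self.intakes),
                            ("nutrients", self.nutrients)):
            if not frame.index.equals(self.participants.index):
                if set(frame.index) != set(self.participants.index):
                    raise SchemaError(
                        f"{name} table subjects do not match participants"
                    )
        if (self.intakes.to_numpy() < 0).any():
            raise SchemaError("negative intake values present")
        if not np.isfinite(self.intakes.to_numpy()).all():
            raise SchemaError("non-finite intake values present")
        return self


def _require_columns(df: pd.DataFrame, required, table: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{table} table is missing mandatory column(s): "
            f"{', '.join(missing)}"
        )


def validate_participants(df: pd.DataFrame) -> None:
    _require_columns(df.reset_index(), PARTICIPANT_COLUMNS, "participants")
    bad_status = set(df["status"]) - {"case", "control"}
    if bad_status:
        raise SchemaError(f"unknown status values: {sorted(bad_status)}")

    counts = df.groupby("pair_id")["status"].agg(
        n_case=lambda s: (s == "case").sum(),
        n_control=lambda s: (s == "control").sum(),
    )
    broken = counts[(counts["n_case"] != 1) | (counts["n_control"] != 1)]
    if len(broken):
        ids = sorted(broken.index.astype(str))
        raise PairingError(
            "pair(s) without exactly one case and one control: "
            + ", ".join(ids),
            pair_ids=ids,
        )

    for col in ("waist_cm", "height_cm", "weight_kg"):
        vals = pd.to_numeric(df[col], errors="coerce")
        if (vals.dropna() <= 0).any():
            raise SchemaError(f"{col} must be strictly positive when present")
    if (pd.to_numeric(df["age"], errors="coerce") <= 17).any():
        raise SchemaError("age must exceed 17 years")


def validate_nutrients(df: pd.DataFrame) -> None:
    _require_columns(df.reset_index(), NUTRIENT_COLUMNS, "nutrients")
    arr = df[["energy_kj", "fat_g", "sfa_g", "added_sugar_g", "alcohol_g"]]
    if not np.isfinite(arr.to_numpy(dtype=float)).all():
        raise SchemaError("nutrient totals must be finite")
    if (df["energy_kj"] <= 0).any():
        raise SchemaError("energy_kj must be strictly positive")
    if (arr.to_numpy(dtype=float) < 0).any():
        raise SchemaError("nutrient totals must be nonnegative")
    if (df["fat_g"] < df["sfa_g"]).any():
        raise SchemaError("saturated fat cannot exceed total fat")


def read_study(participants_path, intakes_path, nutrients_path) -> StudyTable:
    """Read and validate the three study tables.

    Unknown participant columns are preserved but logged. Empty categorical
    cells are normalised to the ``"unknown"`` level.
    """
    participants = pd.read_csv(participants_path, dtype={
        "subject_id": str, "pair_id": str,
    })
    _require_columns(participants, PARTICIPANT_COLUMNS, "participants")
    extra = [c for c in participants.columns if c not in PARTICIPANT_COLUMNS]
    if extra:
        logger.warning("participants: preserving unknown column(s) %s", extra)
    for col in CATEGORICAL_COLUMNS:
        participants[col] = (
            participants[col].astype("object").where(
                participants[col].notna(), "unknown"
            )
        )
    participants = participants.set_index("subject_id")

    intakes = pd.read_csv(intakes_path, dtype={"subject_id": str})
    _require_columns(intakes, ["subject_id"], "intakes")
    intakes = intakes.set_index("subject_id")

    nutrients = pd.read_csv(nutrients_path, dtype={"subject_id": str})
    _require_columns(nutrients, NUTRIENT_COLUMNS, "nutrients")
    nutrients = nutrients.set_index("subject_id")

    study = StudyTable(
        participants=participants,
        intakes=intakes.loc[participants.index],
        nutrients=nutrients.loc[participants.index],
        provenance={
            "participants": str(participants_path),
            "intakes": str(intakes_path),
            "nutrients": str(nutrients_path),
        },
    ).validate()
    logger.info(
        "read_study: %d subjects, %d pairs, %d food items",
        study.n_subjects, study.n_pairs, study.intakes.shape[1],
    )
    return study


def write_study(study: StudyTable, out_dir) -> dict[str, Path]:
    """Write the three study CSVs into ``out_dir``; returns their paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "participants": out / "participants.csv",
        "intakes": out / "intakes.csv",
        "nutrients": out / "nutrients.csv",
    }
    cols = [c for c in PARTICIPANT_COLUMNS if c != "subject_id"]
    extra = [c for c in study.participants.columns if c not in cols]
    study.participants[cols + extra].to_csv(
        paths["participants"], index_label="subject_id"
    )
    study.intakes.to_csv(paths["intakes"], index_label="subject_id")
    study.nutrients[NUTRIENT_COLUMNS[1:]].to_csv(
        paths["nutrients"], index_label="subject_id"
    )
    return paths


def read_mapping(config_path) -> GroupMapping:
    """Parse and validate a YAML food-group mapping config.

    Expected layout::

        schema_version: 1
        items:
          brown_bread:
            dds_group: 1
            families: [starchy]
            starchy_unit_g: 35
            kj_per_g: 10.2

    ``families`` lists at most one scored family (documented exclusivity:
    the scored families partition foods, e.g. an egg item cannot also count
    as dairy); ``starchy`` items must carry ``starchy_unit_g`` > 0.
    """
    with open(config_path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    return mapping_from_dict(raw)


def mapping_from_dict(raw: dict) -> GroupMapping:
    if not isinstance(raw, dict) or "items" not in raw:
        raise MappingError("mapping config must contain an 'items' section")
    version = int(raw.get("schema_version", 1))
    rows = {}
    for item, entry in raw["items"].items():
        entry = entry or {}
        families = list(entry.get("families", []))
        unknown = set(families) - set(FOOD_FAMILIES)
        if unknown:
            raise MappingError(
                f"item {item!r}: unknown food families {sorted(unknown)}"
            )
        if len(families) > 1:
            raise MappingError(
                f"item {item!r} is ambiguous: assigned to multiple scored "
                f"families {sorted(families)}; families are exclusive"
            )
        family = families[0] if families else None
        dds_group = entry.get("dds_group")
        if dds_group is not None:
            dds_group = int(dds_group)
            if not 1 <= dds_group <= 9:
                raise MappingError(
                    f"item {item!r}: dds_group must be 1-9, got {dds_group}"
                )
        unit = entry.get("starchy_unit_g")
        if family == "starchy":
            if unit is None or float(unit) <= 0:
                raise MappingError(
                    f"starchy item {item!r} lacks a positive starchy_unit_g"
                )
            unit = float(unit)
        else:
            unit = np.nan
        rows[str(item)] = {
            "dds_group": np.nan if dds_group is None else float(dds_group),
            "family": family,
            "starchy_unit_g": unit,
            "kj_per_g": float(entry.get("kj_per_g", np.nan)),
        }
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "item"
    return GroupMapping(table=table, schema_version=version)


def compute_bmi(weight_kg, height_cm):
    """Body-mass index in kg/m^2 from measured weight and height.

    Accepts scalars or arrays; all inputs must be strictly positive.
    """
    weight = np.asarray(weight_kg, dtype=float)
    height = np.asarray(height_cm, dtype=float)
    if (weight <= 0).any() or (height <= 0).any():
        raise DomainError("weight and height must be strictly positive")
    bmi = weight / (height / 100.0) ** 2
    return float(bmi) if np.isscalar(weight_kg) else bmi


def is_obese(bmi):
    """Obesity indicator at the conventional BMI >= 30 kg/m^2 cut-point."""
    return np.asarray(bmi, dtype=float) >= OBESITY_BMI if not np.isscalar(bmi) \
        else float(bmi) >= OBESITY_BMI
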