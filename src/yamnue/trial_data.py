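"""Data model, validation and CSV I/O for plant-level field-trial records.

The unit of observation is a single sampled plant, destructively harvested
and separated into organs (leaf, stem, tuber).  Each organ carries fresh
and dry weights in grams and, where assayed, tissue N/P/K concentrations
in mg per g dry matter.  Records are exchanged as long-format CSV with one
row per plant x organ.

A :class:`TrialConfig` holds the trial-level constants needed by the
efficiency indices: fertilizer rates (kg ha^-1) and planting density
(plants ha^-1), from which the per-plant nutrient supply is derived.
"""

from __future__ import annotations

import math
from enum import Enum
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

__all__ = [
    "Organ",
    "Treatment",
    "Nutrient",
    "OrganMeasurement",
    "PlantRecord",
    "TrialConfig",
    "SchemaError",
    "TrialValidationError",
    "CSV_COLUMNS",
    "read_trial",
    "write_trial",
    "records_to_frame",
]


class Organ(str, Enum):
    """Plant part separated at harvest."""

    LEAF = "leaf"
    STEM = "stem"
    TUBER = "tuber"


class Treatment(str, Enum):
    """Main-plot soil fertility level: zero input vs NPK fertilizer input."""

    NON_F = "non-F"
    PLUS_F = "+F"


class Nutrient(str, Enum):
    N = "N"
    P = "P"
    K = "K"


#: Column order of the plant-level CSV interchange format.
CSV_COLUMNS = [
    "genotype",
    "block",
    "treatment",
    "plant_id",
    "organ",
    "fresh_weight_g",
    "dry_weight_g",
    "conc_N_mg_g",
    "conc_P_mg_g",
    "conc_K_mg_g",
]

#: Upper plausibility bound for a tissue concentration (mg g^-1 dry matter).
MAX_CONC_MG_G = 1000.0


class SchemaError(ValueError):
    """The CSV header does not match the documented schema."""


class TrialValidationError(ValueError):
    """One or more rows violate record invariants.

    Attributes
    ----------
    errors : list of (row, message)
        ``row`` is the 1-based data-row number (header excluded).
    """

    def __init__(self, errors: Sequence[tuple[int, str]]):
        self.errors = list(errors)
        lines = "; ".join(f"row {r}: {m}" for r, m in self.errors)
        super().__init__(f"invalid trial data ({len(self.errors)} problem(s)): {lines}")


class OrganMeasurement(BaseModel):
    """Weights and tissue concentrations for one plant part.

    For the tuber, ``fresh_weight_g`` is the total fresh tuber weight and
    ``dry_weight_g`` the total dry tuber weight (fresh weight x percent dry
    matter / 100).  Concentrations are optional: in the reference trial
    design only leaf and tuber tissue were assayed.
    """

    model_config = ConfigDict(frozen=True)

    organ: Organ
    fresh_weight_g: Optional[float] = Field(default=None, ge=0)
    dry_weight_g: float = Field(ge=0)
    conc_N_mg_g: Optional[float] = Field(default=None, ge=0, lt=MAX_CONC_MG_G)
    conc_P_mg_g: Optional[float] = Field(default=None, ge=0, lt=MAX_CONC_MG_G)
    conc_K_mg_g: Optional[float] = Field(default=None, ge=0, lt=MAX_CONC_MG_G)

    @field_validator("fresh_weight_g", "dry_weight_g", "conc_N_mg_g", "conc_P_mg_g", "conc_K_mg_g")
    @classmethod
    def _finite(cls, v):
        if v is not None and not math.isfinite(v):
            raise ValueError("value must be finite")
        return v

    @model_validator(mode="after")
    def _dry_le_fresh(self):
        if self.fresh_weight_g is not None and self.dry_weight_g > self.fresh_weight_g + 1e-9:
            raise ValueError(
                f"{self.organ.value}: dry weight {self.dry_weight_g} g exceeds "
                f"fresh weight {self.fresh_weight_g} g"
            )
        return self

    def concentration(self, nutrient: Nutrient) -> Optional[float]:
        return getattr(self, f"conc_{nutrient.value}_mg_g")

    def has_concentrations(self) -> bool:
        return any(self.concentration(n) is not None for n in Nutrient)


class PlantRecord(BaseModel):
    """One sampled plant: identity plus its organ measurements."""

    model_config = ConfigDict(frozen=True)

    genotype: str
    block: int = Field(ge=1)
    treatment: Treatment
    plant_id: str
    organs: tuple[OrganMeasurement, ...]

    @model_validator(mode="after")
    def _one_per_organ(self):
        seen = [o.organ for o in self.organs]
        if len(seen) != len(set(seen)):
            raise ValueError(f"duplicate organ entries for plant {self.plant_id}")
        return self

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.genotype, self.block, self.treatment.value, self.plant_id)

    def organ(self, organ: Organ) -> Optional[OrganMeasurement]:
        for o in self.organs:
            if o.organ is organ:
                return o
        return None


class TrialConfig(BaseModel):
    """Trial-level constants: fertilizer rates and planting density.

    ``per_plant_supply`` converts an areal application rate into the
    nutrient supply F in grams per plant used by the apparent recovery
    efficiency: F = rate (kg ha^-1) x 1000 / density (plants ha^-1).
    """

    rate_N_kg_ha: float = Field(ge=0)
    rate_P_kg_ha: float = Field(ge=0)
    rate_K_kg_ha: float = Field(ge=0)
    plant_density_ha: float = Field(gt=0)
    n_blocks: int = Field(ge=2)

    def per_plant_supply(self, nutrient: Nutrient | str) -> float:
        """Nutrient supply in g plant^-1 for one of N, P, K."""
        nutrient = Nutrient(nutrient)
        rate = getattr(self, f"rate_{nutrient.value}_kg_ha")
        return rate * 1000.0 / self.plant_density_ha

    @classmethod
    def from_yaml(cls, path: str | Path) -> "TrialConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, dict):
            raise SchemaError(f"trial config {path} must be a YAML mapping")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.model_dump(), fh, sort_keys=False)


def _parse_float(value, allow_missing: bool) -> Optional[float]:
    if value is None or (isinstance(value, float) and math.isnan(value)) or value == "":
        if allow_missing:
            return None
        raise ValueError("missing value")
    return float(value)


def read_trial(path: str | Path, config: TrialConfig | None = None) -> list[PlantRecord]:
    """Read and validate a plant-level trial CSV.

    Parameters
    ----------
    path :
        CSV file in the long plant x organ schema (see :data:`CSV_COLUMNS`).
    config :
        Optional trial configuration; when given, block numbers are checked
        against ``config.n_blocks``.

    Returns
    -------
    list of PlantRecord, in order of first appearance in the file.

    Raises
    ------
    SchemaError
        If a required column is missing.
    TrialValidationError
        If any row violates an invariant; every offending row is reported
        with its 1-based data-row number.
    """
    path = Path(path)
    frame = pd.read_csv(
        path,
        dtype={"genotype": str, "treatment": str, "plant_id": str, "organ": str},
        float_precision="round_trip",  # lossless write -> read
    )
    missing = [c for c in CSV_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {', '.join(missing)}")
    if frame.empty:
        raise TrialValidationError([(0, "file contains no data rows")])

    errors: list[tuple[int, str]] = []
    # plant key -> list of (row, OrganMeasurement)
    plants: dict[tuple, list[tuple[int, OrganMeasurement]]] = {}
    plant_meta: dict[tuple, dict] = {}
    seen_organ: set[tuple] = set()

    for idx, row in enumerate(frame.itertuples(index=False), start=1):
        try:
            treatment = Treatment(row.treatment)
            organ = Organ(row.organ)
            block = int(row.block)
            measurement = OrganMeasurement(
                organ=organ,
                fresh_weight_g=_parse_float(row.fresh_weight_g, allow_missing=True),
                dry_weight_g=_parse_float(row.dry_weight_g, allow_missing=False),
                conc_N_mg_g=_parse_float(row.conc_N_mg_g, allow_missing=True),
                conc_P_mg_g=_parse_float(row.conc_P_mg_g, allow_missing=True),
                conc_K_mg_g=_parse_float(row.conc_K_mg_g, allow_missing=True),
            )
        except (ValueError, TypeError) as exc:
            errors.append((idx, _compact_error(exc)))
            continue
        if config is not None and block > config.n_blocks:
            errors.append((idx, f"block {block} exceeds configured n_blocks={config.n_blocks}"))
            continue
        key = (str(row.genotype), block, treatment.value, str(row.plant_id))
        organ_key = key + (organ.value,)
        if organ_key in seen_organ:
            errors.append((idx, f"duplicate entry for plant {key} organ {organ.value}"))
            continue
        seen_organ.add(organ_key)
        plants.setdefault(key, []).append((idx, measurement))
        plant_meta.setdefault(
            key,
            {"genotype": str(row.genotype), "block": block, "treatment": treatment, "plant_id": str(row.plant_id)},
        )

    if errors:
        raise TrialValidationError(errors)

    records = []
    for key, organ_rows in plants.items():
        meta = plant_meta[key]
        try:
            records.append(PlantRecord(organs=tuple(m for _, m in organ_rows), **meta))
        except ValueError as exc:  # pragma: no cover - duplicates caught above
            errors.append((organ_rows[0][0], _compact_error(exc)))
    if errors:
        raise TrialValidationError(errors)
    return records


def _compact_error(exc: Exception) -> str:
    """First informative line of a (possibly multi-line pydantic) error."""
    text = str(exc)
    lines = [ln.strip() for ln in text.splitlines() if ln.strip()]
    if len(lines) >= 2 and "validation error" in lines[0]:
        return "; ".join(lines[1:3])
    return lines[0] if lines else repr(exc)


def records_to_frame(records: Iterable[PlantRecord]) -> pd.DataFrame:
    """Flatten records into the long plant x organ CSV schema."""
    rows = []
    for rec in records:
        for org in rec.organs:
            rows.append(
                {
                    "genotype": rec.genotype,
                    "block": rec.block,
                    "treatment": rec.treatment.value,
                    "plant_id": rec.plant_id,
                    "organ": org.organ.value,
                    "fresh_weight_g": org.fresh_weight_g,
                    "dry_weight_g": org.dry_weight_g,
                    "conc_N_mg_g": org.conc_N_mg_g,
                    "conc_P_mg_g": org.conc_P_mg_g,
                    "conc_K_mg_g": org.conc_K_mg_g,
                }
            )
    return pd.DataFrame(rows, columns=CSV_COLUMNS)


def write_trial(records: Sequence[PlantRecord], path: str | Path) -> None:
    """Write records to CSV, losslessly re-readable by :func:`read_trial`."""
    records = list(records)
    if not records:
        raise ValueError("cannot write an empty record collection")
    frame = records_to_frame(records)
    # repr-based float formatting keeps the round trip exact
    frame.to_csv(path, index=False)
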