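"""Patient-level schema for a multicentre SPDP registry.

One row per patient in whom a minimally invasive spleen-preserving distal
pancreatectomy (SPDP) was *intended*; patients converted to splenectomy
intraoperatively stay in the table (intention-to-treat framing). Every
covariate and outcome field admits a MISSING value, encoded as an empty
cell in CSV and as ``pd.NA`` in memory.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import pandas as pd

# Ordinal coding of the Clavien-Dindo complication grades. Grade 0 means an
# uneventful course; >= I is any complication, >= IIIa is major morbidity.
CLAVIEN_DINDO_LEVELS = ("0", "I", "II", "IIIa", "IIIb", "IVa", "IVb", "V")
CLAVIEN_DINDO_RANK = {g: i for i, g in enumerate(CLAVIEN_DINDO_LEVELS)}

ASA_LEVELS = ("I", "II", "III", "IV", "V")
ASA_RANK = {g: i + 1 for i, g in enumerate(ASA_LEVELS)}

APPROACHES = ("laparoscopic", "robotic")
SEXES = ("female", "male")
PRESERVATION_METHODS = ("kimura", "warshaw", "splenectomy")
POPF_GRADES = ("none", "BL", "B", "C")

FieldKind = Literal["id", "int", "float", "bool", "enum"]


@dataclass(frozen=True)
class FieldDef:
    name: str
    kind: FieldKind
    levels: tuple[str, ...] | None = None
    required: bool = False  # never MISSING


# Column order is the canonical CSV column order.
FIELDS: tuple[FieldDef, ...] = (
    FieldDef("patient_id", "id", required=True),
    FieldDef("centre_id", "id", required=True),
    FieldDef("year", "int", required=True),
    FieldDef("approach", "enum", APPROACHES),
    FieldDef("age", "float"),
    FieldDef("sex", "enum", SEXES),
    FieldDef("asa_grade", "enum", ASA_LEVELS),
    FieldDef("bmi", "float"),
    FieldDef("prev_abdominal_surgery", "bool"),
    FieldDef("prev_major_abdominal_surgery", "bool"),
    FieldDef("extended_or_multivisceral", "bool"),
    FieldDef("chf_recent", "bool"),
    FieldDef("angina_recent", "bool"),
    FieldDef("mi_recent", "bool"),
    FieldDef("pci_or_cardiac_surgery", "bool"),
    FieldDef("atrial_fibrillation", "bool"),
    FieldDef("chronic_renal_failure", "bool"),
    FieldDef("copd_fev1_lt80", "bool"),
    FieldDef("noac", "bool"),
    FieldDef("vka", "bool"),
    FieldDef("clopidogrel", "bool"),
    FieldDef("diabetes_2plus_oad_or_insulin", "bool"),
    FieldDef("tumour_size_gt5cm", "bool"),
    FieldDef("preservation_method", "enum", PRESERVATION_METHODS),
    FieldDef("op_duration_min", "float"),
    FieldDef("blood_loss_ml", "float"),
    FieldDef("conversion", "bool"),
    FieldDef("spleen_preservation_failed", "bool"),
    FieldDef("clavien_dindo", "enum", CLAVIEN_DINDO_LEVELS),
    FieldDef("popf_grade", "enum", POPF_GRADES),
    FieldDef("los_days", "float"),
    FieldDef("readmission_90d", "bool"),
    FieldDef("mortality_90d", "bool"),
)

COLUMNS: tuple[str, ...] = tuple(f.name for f in FIELDS)
FIELD_BY_NAME = {f.name: f for f in FIELDS}


def _pandas_dtype(field: FieldDef) -> str:
    return {
        "id": "string",
        "int": "Int64",
        "float": "Float64",
        "bool": "boolean",
        "enum": "string",
    }[field.kind]


DTYPES = {f.name: _pandas_dtype(f) for f in FIELDS}


def empty_frame() -> pd.DataFrame:
    """An empty registry DataFrame with the canonical columns and dtypes."""
    return pd.DataFrame({c: pd.Series([], dtype=DTYPES[c]) for c in COLUMNS})


def coerce_frame(df: pd.DataFrame) -> pd.DataFrame:
    """Reorder to canonical column order and cast to nullable dtypes."""
    out = df.loc[:, list(COLUMNS)].copy()
    for c in COLUMNS:
        out[c] = out[c].astype(DTYPES[c])
    return out.reset_index(drop=True)


def cd_at_least(series: pd.Series, grade: str) -> pd.Series:
    """Boolean series: Clavien-Dindo grade >= `grade`, MISSING preserved."""
    rank = series.map(CLAVIEN_DINDO_RANK).astype("Int64")
    return (rank >= CLAVIEN_DINDO_RANK[grade]).astype("boolean")


def asa_at_least(series: pd.Series, grade: str) -> pd.Series:
    rank = series.map(ASA_RANK).astype("Int64")
    return (rank >= ASA_RANK[grade]).astype("boolean")
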