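import numpy as np
import pandas as pd
import pytest

from spdp_bench import registry as reg
from spdp_bench import schema
from spdp_bench.synthetic_registry import SyntheticConfig

BASE_ROW = {
    "patient_id": "P1", "centre_id": "C1", "year": 2015,
    "approach": "laparoscopic", "age": 60.0, "sex": "female",
    "asa_grade": "II", "bmi": 24.0,
    "prev_abdominal_surgery": False, "prev_major_abdominal_surgery": False,
    "extended_or_multivisceral": False, "chf_recent": False,
    "angina_recent": False, "mi_recent": False,
    "pci_or_cardiac_surgery": False, "atrial_fibrillation": False,
    "chronic_renal_failure": False, "copd_fev1_lt80": False,
    "noac": False, "vka": False, "clopidogrel": False,
    "diabetes_2plus_oad_or_insulin": False, "tumour_size_gt5cm": False,
    "preservation_method": "kimura", "op_duration_min": 180.0,
    "blood_loss_ml": 100.0, "conversion": False,
    "spleen_preservation_failed": False, "clavien_dindo": "0",
    "popf_grade": "none", "los_days": 7.0, "readmission_90d": False,
    "mortality_90d": False,
}


def make_rows(n, **overrides):
    """n copies of the benign base row with per-column overrides.

    An override may be a scalar (applied to all rows) or a list of length n.
    patient_id is always made unique.
    """
    rows = []
    for i in range(n):
        row = dict(BASE_ROW)
        row["patient_id"] = f"P{i + 1:04d}"
        for col, val in overrides.items():
            row[col] = val[i] if isinstance(val, (list, tuple)) else val
        rows.append(row)
    return rows


def make_table(rows, strict=False) -> reg.RegistryTable:
    df = pd.DataFrame(rows)
    for fdef in schema.FIELDS:
        if fdef.name not in df.columns:
            df[fdef.name] = pd.NA
    return reg.from_frame(df, provenance="test", strict=strict)


def small_config(seed=0, **overrides) -> SyntheticConfig:
    """A small, fast synthetic configuration for property tests."""
    defaults = dict(n_centres=8, volume_mean=14.0, volume_dispersion=2.0,
                    centre_span_mean=1.5, seed=seed)
    defaults.update(overrides)
    return SyntheticConfig(**defaults)


@pytest.fixture
def base_table():
    return make_table(make_rows(6))


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)
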