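"""Low-risk patient eligibility and centre-volume eligibility.

The best-patient-in-best-centre benchmark is computed in a predefined
low-risk cohort treated in high-volume centres. A patient is low-risk when
none of the surgical, comorbidity or medication exclusion criteria fires;
a centre is volume-eligible when its mean annual caseload over the years it
contributed data reaches ``min_annual`` (default 10/year), with an optional
stricter rule requiring every contributing year to reach the threshold.

A record with MISSING data in a field a criterion needs cannot be shown to
be low-risk; it is flagged indeterminate and excluded from the low-risk
cohort (counted separately in the attrition report).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import schema
from .registry import RegistryTable

# criterion id -> (label, columns consulted)
CRITERIA: dict[str, tuple[str, tuple[str, ...]]] = {
    "extended_resection": (
        "Extended distal pancreatectomy or multivisceral resection",
        ("extended_or_multivisceral",)),
    "prev_major_surgery": (
        "Previous major abdominal surgery (bariatric or liver surgery)",
        ("prev_major_abdominal_surgery",)),
    "asa_ge_iii": ("ASA fitness grade >= III", ("asa_grade",)),
    "bmi_ge_35": ("BMI >= 35 kg/m2", ("bmi",)),
    "cardiac_disease": (
        "Cardiac disease (recent CHF, angina, MI, PCI/cardiac surgery, or "
        "atrial fibrillation)",
        ("chf_recent", "angina_recent", "mi_recent",
         "pci_or_cardiac_surgery", "atrial_fibrillation")),
    "chronic_renal_failure": (
        "Chronic renal failure (MDRD >= stage 3)", ("chronic_renal_failure",)),
    "copd": ("COPD with FEV1 < 80%", ("copd_fev1_lt80",)),
    "anticoagulants": (
        "Anticoagulant use (NOAC, VKA or clopidogrel)",
        ("noac", "vka", "clopidogrel")),
    "diabetes": (">= 2 oral antidiabetics or insulin",
                 ("diabetes_2plus_oad_or_insulin",)),
    "age_lt_18": ("Age < 18 years", ("age",)),
}


@dataclass
class EligibilityDecision:
    patient_id: str
    eligible: bool
    failed_criteria: list[str]
    indeterminate: bool = False

    def __post_init__(self) -> None:
        assert self.eligible == (not self.failed_criteria and not self.indeterminate)


@dataclass
class AttritionReport:
    """Counts of low-risk exclusions per criterion plus centre-volume attrition."""

    n_input: int = 0
    n_low_risk: int = 0
    n_indeterminate: int = 0
    excluded_by_criterion: dict[str, int] = field(default_factory=dict)
    centres_input: int = 0
    centres_eligible: int = 0
    n_removed_centre_volume: int = 0
    n_output: int = 0

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"criterion": cid, "label": CRITERIA[cid][0],
             "n_excluded": self.excluded_by_criterion.get(cid, 0)}
            for cid in CRITERIA
        ]
        rows.append({"criterion": "indeterminate",
                     "label": "MISSING data in a field needed by a criterion",
                     "n_excluded": self.n_indeterminate})
        rows.append({"criterion": "centre_volume",
                     "label": "Treated in a centre below the volume threshold",
                     "n_excluded": self.n_removed_centre_volume})
        return pd.DataFrame(rows)


def _criterion_fires(df: pd.DataFrame) -> dict[str, pd.Series]:
    """Boolean (nullable) series per criterion: True fired, NA indeterminate."""
    fired: dict[str, pd.Series] = {}
    fired["extended_resection"] = df["extended_or_multivisceral"]
    fired["prev_major_surgery"] = df["prev_major_abdominal_surgery"]
    fired["asa_ge_iii"] = schema.asa_at_least(df["asa_grade"], "III")
    fired["bmi_ge_35"] = (df["bmi"] >= 35).mask(df["bmi"].isna()).astype("boolean")
    cardiac_cols = CRITERIA["cardiac_disease"][1]
    fired["cardiac_disease"] = _any_flag(df, cardiac_cols)
    fired["chronic_renal_failure"] = df["chronic_renal_failure"]
    fired["copd"] = df["copd_fev1_lt80"]
    fired["anticoagulants"] = _any_flag(df, CRITERIA["anticoagulants"][1])
    fired["diabetes"] = df["diabetes_2plus_oad_or_insulin"]
    fired["age_lt_18"] = (df["age"] < 18).mask(df["age"].isna()).astype("boolean")
    return {k: v.astype("boolean") for k, v in fired.items()}


def _any_flag(df: pd.DataFrame, cols: tuple[str, ...]) -> pd.Series:
    """OR over flags: True if any True; NA only if none True and any missing."""
    stacked = df[list(cols)].astype("boolean")
    any_true = stacked.fillna(False).any(axis=1)
    any_na = stacked.isna().any(axis=1)
    return any_true.mask(~any_true & any_na).astype("boolean")


def low_risk_table(table: RegistryTable) -> pd.DataFrame:
    """Vectorised eligibility: one row per patient with per-criterion flags."""
    fired = _criterion_fires(table.df)
    out = pd.DataFrame({"patient_id": table.df["patient_id"]})
    for cid, series in fired.items():
        out[cid] = series
    flags = out[list(CRITERIA)]
    out["any_fired"] = flags.fillna(False).any(axis=1)
    out["indeterminate"] = ~out["any_fired"] & flags.isna().any(axis=1)
    out["eligible"] = ~out["any_fired"] & ~out["indeterminate"]
    return out


def low_risk_filter(record) -> EligibilityDecision:
    """Eligibility of a single patient record (row of a registry frame)."""
    if isinstance(record, pd.Series):
        df = record.to_frame().T
        df = df.astype({c: schema.DTYPES[c] for c in df.columns if c in schema.DTYPES})
    else:
        df = pd.DataFrame([record._asdict() if hasattr(record, "_asdict") else dict(record)])
        df = df.astype({c: schema.DTYPES[c] for c in df.columns if c in schema.DTYPES})
    fired = _criterion_fires(df)
    failed = [cid for cid, s in fired.items() if bool(s.fillna(False).iloc[0])]
    indeterminate = not failed and any(bool(s.isna().iloc[0]) for s in fired.values())
    return EligibilityDecision(
        patient_id=str(df["patient_id"].iloc[0]),
        eligible=not failed and not indeterminate,
        failed_criteria=failed,
        indeterminate=indeterminate,
    )


def centre_volume_summary(table: RegistryTable) -> pd.DataFrame:
    """Per-centre caseload, distinct contributing years and mean annual volume."""
    g = table.df.groupby("centre_id", observed=True)
    out = pd.DataFrame({
        "n_records": g.size(),
        "n_years": g["year"].nunique(),
        "min_annual_volume": g.apply(
            lambda s: s.groupby("year").size().min(), include_groups=False),
    })
    out["mean_annual_volume"] = out["n_records"] / out["n_years"]
    return out.reset_index()


def centre_volume_filter(table: RegistryTable, min_annual: float = 10,
                         rule: str = "mean") -> set[str]:
    """Centres meeting the annual-volume criterion.

    rule='mean': caseload / distinct contributing years >= min_annual.
    rule='every_year': every contributing year individually >= min_annual.
    """
    summary = centre_volume_summary(table)
    if rule == "mean":
        ok = summary["mean_annual_volume"] >= min_annual
    elif rule == "every_year":
        ok = summary["min_annual_volume"] >= min_annual
    else:
        raise ValueError(f"unknown volume rule {rule!r}")
    return set(summary.loc[ok, "centre_id"])


def apply_low_risk_cohort(table: RegistryTable, min_annual: float = 10,
                          volume_rule: str = "mean",
                          ) -> tuple[RegistryTable, AttritionReport]:
    """Restrict to low-risk patients in volume-eligible centres.

    Patients in an ineligible centre are removed regardless of their own
    eligibility. Returns the filtered table and an attrition report with
    exclusion counts per criterion (a patient can fail several criteria and
    is counted under each).
    """
    report = AttritionReport(n_input=len(table))
    elig = low_risk_table(table)
    for cid in CRITERIA:
        report.excluded_by_criterion[cid] = int(elig[cid].fillna(False).sum())
    report.n_indeterminate = int(elig["indeterminate"].sum())
    report.n_low_risk = int(elig["eligible"].sum())

    centres = centre_volume_filter(table, min_annual=min_annual, rule=volume_rule)
    report.centres_input = len(table.centre_ids)
    report.centres_eligible = len(centres)
    in_centre = table.df["centre_id"].isin(centres)
    keep = np.asarray(elig["eligible"]) & np.asarray(in_centre)
    report.n_removed_centre_volume = int((np.asarray(elig["eligible"]) & ~np.asarray(in_centre)).sum())
    report.n_output = int(keep.sum())
    if report.n_output == 0:
        warnings.warn("low-risk cohort is empty after filtering")
    low_risk = table.subset(pd.Series(keep), provenance=f"{table.provenance}[low-risk]")
    return low_risk, report
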