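"""Registry I/O, validation and cohort summary tables.

The registry is a patient-level CSV (UTF-8, header row, one row per intended
SPDP). MISSING is encoded as an empty cell; no other sentinel is accepted.
Reading validates the schema invariants either strictly (any violation
aborts) or leniently (offending fields are blanked to MISSING and counted
in a validation report).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd

from . import schema
from .outcomes import OUTCOMES_BY_NAME, OutcomeSpec

_TRUE = {"1", "true", "True", "TRUE"}
_FALSE = {"0", "false", "False", "FALSE"}


class RegistryError(ValueError):
    """Fatal problem with a registry file or table."""


class ValidationError(RegistryError):
    """A schema invariant violated in strict mode; names the rule."""


@dataclass
class ValidationReport:
    n_records: int = 0
    violations: dict[str, int] = field(default_factory=dict)
    missing_counts: dict[str, int] = field(default_factory=dict)

    def count(self, rule: str, n: int = 1) -> None:
        if n:
            self.violations[rule] = self.violations.get(rule, 0) + int(n)

    def to_text(self) -> str:
        lines = [f"records: {self.n_records}", "violations:"]
        if not self.violations:
            lines.append("  none")
        for rule, n in sorted(self.violations.items()):
            lines.append(f"  {rule}: {n}")
        lines.append("missing values per field:")
        for col in schema.COLUMNS:
            n = self.missing_counts.get(col, 0)
            if n:
                lines.append(f"  {col}: {n}")
        if not any(self.missing_counts.values()):
            lines.append("  none")
        return "\n".join(lines)


@dataclass
class RegistryTable:
    """A validated registry: typed DataFrame plus provenance."""

    df: pd.DataFrame
    provenance: str = "<memory>"
    report: ValidationReport | None = None

    def __len__(self) -> int:
        return len(self.df)

    def __post_init__(self) -> None:
        if self.df["patient_id"].duplicated().any():
            dupes = self.df["patient_id"][self.df["patient_id"].duplicated()]
            raise RegistryError(
                f"duplicated patient_id: {sorted(set(dupes))[:5]}"
            )

    @property
    def centre_ids(self) -> list[str]:
        return sorted(self.df["centre_id"].dropna().unique())

    def subset(self, mask: pd.Series, provenance: str | None = None) -> "RegistryTable":
        return RegistryTable(
            self.df.loc[np.asarray(mask, dtype=bool)].reset_index(drop=True),
            provenance=provenance or self.provenance,
        )

    def stratum(self, approach: str) -> "RegistryTable":
        """Restrict to one approach; 'all' returns the table unchanged."""
        if approach == "all":
            return self
        if approach not in schema.APPROACHES:
            raise ValueError(f"unknown approach {approach!r}")
        return self.subset(
            (self.df["approach"] == approach).fillna(False),
            provenance=f"{self.provenance}[{approach}]",
        )


# ---------------------------------------------------------------------------
# parsing and validation


def _parse_column(raw: pd.Series, fdef: schema.FieldDef, report: ValidationReport,
                  strict: bool) -> pd.Series:
    """Parse one string column to its typed series, blanking bad cells."""
    s = raw.astype("string").str.strip()
    missing = s.isna() | (s == "")
    if fdef.kind == "id":
        out = s.mask(missing)
    elif fdef.kind in ("int", "float"):
        out = pd.to_numeric(s.mask(missing), errors="coerce")
        bad = out.isna() & ~missing
        _flag(bad, f"{fdef.name}: not numeric", report, strict)
        out = pd.Series(out, dtype=schema.DTYPES[fdef.name])
    elif fdef.kind == "bool":
        out = pd.Series(pd.NA, index=s.index, dtype="boolean")
        out[s.isin(_TRUE)] = True
        out[s.isin(_FALSE)] = False
        bad = out.isna() & ~missing
        _flag(bad, f"{fdef.name}: not a 0/1 flag", report, strict)
    else:  # enum
        bad = ~missing & ~s.isin(fdef.levels)
        _flag(bad, f"{fdef.name}: not in {fdef.levels}", report, strict)
        out = s.mask(missing | bad)
    return out.astype(schema.DTYPES[fdef.name])


def _flag(bad: pd.Series, rule: str, report: ValidationReport, strict: bool) -> None:
    n = int(bad.sum())
    if not n:
        return
    if strict:
        raise ValidationError(f"{rule} ({n} row(s))")
    report.count(rule, n)


def validate_frame(df: pd.DataFrame, strict: bool = False,
                   report: ValidationReport | None = None) -> tuple[pd.DataFrame, ValidationReport]:
    """Enforce the row-level invariants on a typed frame.

    Range rules: age >= 18, bmi > 0, op_duration_min > 0, blood_loss_ml >= 0,
    los_days >= 1. Cross-field rules: spleen_preservation_failed is true iff
    preservation_method is splenectomy (both observed); 90-day mortality
    implies Clavien-Dindo grade V (both observed). In lenient mode offending
    fields become MISSING and the rule is counted.
    """
    report = report or ValidationReport()
    report.n_records = len(df)
    df = df.copy()

    for col in ("patient_id", "centre_id", "year"):
        bad = df[col].isna()
        _flag(bad, f"{col}: required, must not be missing", report, strict)
        if bad.any():
            df = df.loc[~bad].reset_index(drop=True)

    range_rules = [
        ("age", df["age"] < 18, "age: must be >= 18"),
        ("bmi", df["bmi"] <= 0, "bmi: must be > 0"),
        ("op_duration_min", df["op_duration_min"] <= 0,
         "op_duration_min: must be > 0"),
        ("blood_loss_ml", df["blood_loss_ml"] < 0,
         "blood_loss_ml: must be >= 0"),
        ("los_days", df["los_days"] < 1, "los_days: must be >= 1"),
    ]
    for col, bad, rule in range_rules:
        bad = bad.fillna(False)
        _flag(bad, rule, report, strict)
        df.loc[bad, col] = pd.NA

    failed = df["spleen_preservation_failed"]
    method = df["preservation_method"]
    mismatch = (
        failed.notna() & method.notna()
        & (failed != (method == "splenectomy"))
    )
    _flag(mismatch, "spleen_preservation_failed: inconsistent with "
          "preservation_method", report, strict)
    df.loc[mismatch, ["spleen_preservation_failed", "preservation_method"]] = pd.NA

    dead = df["mortality_90d"]
    cd = df["clavien_dindo"]
    bad_death = (dead.fillna(False)) & cd.notna() & (cd != "V")
    _flag(bad_death, "mortality_90d: death requires Clavien-Dindo grade V",
          report, strict)
    df.loc[bad_death, ["mortality_90d", "clavien_dindo"]] = pd.NA

    for col in schema.COLUMNS:
        report.missing_counts[col] = int(df[col].isna().sum())
    return df, report


def from_frame(df: pd.DataFrame, provenance: str = "<memory>",
               strict: bool = False) -> RegistryTable:
    """Validate an already-typed (or convertible) frame into a RegistryTable."""
    df = schema.coerce_frame(df)
    df, report = validate_frame(df, strict=strict)
    return RegistryTable(df, provenance=provenance, report=report)


def read_registry(path: str | Path, strict: bool = False) -> RegistryTable:
    """Read and validate a registry CSV.

    Unknown or absent columns and duplicated patient_id are always fatal;
    other invariant violations abort only in strict mode.
    """
    path = Path(path)
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    unknown = [c for c in raw.columns if c not in schema.FIELD_BY_NAME]
    if unknown:
        raise RegistryError(f"unknown column(s): {unknown}")
    absent = [c for c in schema.COLUMNS if c not in raw.columns]
    if absent:
        raise RegistryError(f"missing column(s): {absent}")

    report = ValidationReport()
    typed = {}
    for fdef in schema.FIELDS:
        typed[fdef.name] = _parse_column(raw[fdef.name], fdef, report, strict)
    df = pd.DataFrame(typed)[list(schema.COLUMNS)]
    df, report = validate_frame(df, strict=strict, report=report)
    return RegistryTable(df, provenance=str(path), report=report)


def write_registry(table: RegistryTable, path: str | Path) -> None:
    """Write the registry CSV (MISSING as empty cell, flags as 1/0)."""
    out = table.df.copy()
    for fdef in schema.FIELDS:
        if fdef.kind == "bool":
            out[fdef.name] = table.df[fdef.name].map(
                {True: "1", False: "0"}).astype("string")
    out.to_csv(path, index=False, na_rep="")


# ---------------------------------------------------------------------------
# outcome extraction


def extract_outcome(table: RegistryTable, spec: OutcomeSpec | str) -> pd.Series:
    """Per-patient outcome values with MISSING preserved.

    The non-missing subset defines the outcome's patient pool: a patient with
    missing data for an outcome is excluded from that outcome's benchmark
    only, not from the registry.
    """
    if isinstance(spec, str):
        spec = OUTCOMES_BY_NAME[spec]
    elif spec.name not in OUTCOMES_BY_NAME:
        raise KeyError(f"not one of the ten benchmark outcomes: {spec.name!r}")
    return spec.extract(table.df)


# ---------------------------------------------------------------------------
# cohort summary (baseline-characteristics / outcomes table)


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal half-up rounding, matching clinical-table presentation."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


_CONTINUOUS_SUMMARY = (
    ("age", "Age (years)"),
    ("bmi", "BMI (kg/m2)"),
    ("op_duration_min", "Duration of operation (min)"),
    ("blood_loss_ml", "Blood loss (ml)"),
    ("los_days", "Duration of hospital stay (days)"),
)


def _categorical_rows(df: pd.DataFrame) -> list[tuple[str, str, pd.Series]]:
    """(variable, level, event-flag series) for each count/% row."""
    rows = [
        ("sex", "female", (df["sex"] == "female").mask(df["sex"].isna())),
        ("asa_grade", "I-II",
         (~schema.asa_at_least(df["asa_grade"], "III")).astype("boolean")),
        ("prev_abdominal_surgery", "true", df["prev_abdominal_surgery"]),
        ("tumour_size_gt5cm", "true", df["tumour_size_gt5cm"]),
        ("conversion", "true", df["conversion"]),
        ("spleen_preservation_failed", "true", df["spleen_preservation_failed"]),
        ("spleen_preserved", "true",
         (~df["spleen_preservation_failed"].astype("boolean"))),
        ("overall_morbidity", "true", schema.cd_at_least(df["clavien_dindo"], "I")),
        ("major_morbidity", "true", schema.cd_at_least(df["clavien_dindo"], "IIIa")),
        ("cr_popf", "true",
         df["popf_grade"].isin(["B", "C"]).mask(df["popf_grade"].isna())),
        ("readmission_90d", "true", df["readmission_90d"]),
        ("mortality_90d", "true", df["mortality_90d"]),
    ]
    # preservation technique is conditional on successful preservation: its
    # denominator is the patients with a known spleen-preserving method
    preserved = df["preservation_method"].isin(["kimura", "warshaw"])
    for level in ("warshaw", "kimura"):
        flag = (df["preservation_method"] == level).mask(~preserved)
        rows.append(("preservation_method", level, flag))
    return [(var, level, flag.astype("boolean")) for var, level, flag in rows]


def summarize_cohort(table: RegistryTable, group_by: str = "approach") -> pd.DataFrame:
    """Cohort summary in the style of a baseline/outcome characteristics table.

    One tidy row per (variable, level, group): counts with percentages for
    categorical fields (denominator = per-field non-missing count; rounded
    half-up to one decimal) and median with quartiles for the skewed
    continuous fields. Groups are the approach strata plus 'overall'.
    """
    if len(table) == 0:
        raise RegistryError("cannot summarize an empty registry")
    df = table.df
    groups: list[tuple[str, pd.DataFrame]] = []
    for level in schema.APPROACHES:
        sub = df[(df[group_by] == level).fillna(False)]
        if len(sub) == 0:
            warnings.warn(f"group {level!r} has no records; omitted")
            continue
        groups.append((level, sub))
    groups.append(("overall", df))

    out: list[dict] = []
    total = len(df)
    for level, sub in groups:
        if level != "overall":
            out.append({
                "variable": "approach", "level": level, "group": "overall",
                "n": len(sub), "denominator": total,
                "percent": round_half_up(100 * len(sub) / total, 1),
                "median": np.nan, "q1": np.nan, "q3": np.nan,
            })
    for level, sub in groups:
        for var, lab, flag in _categorical_rows(sub):
            denom = int(flag.notna().sum())
            n = int(flag.fillna(False).sum())
            out.append({
                "variable": var, "level": lab, "group": level,
                "n": n, "denominator": denom,
                "percent": round_half_up(100 * n / denom, 1) if denom else np.nan,
                "median": np.nan, "q1": np.nan, "q3": np.nan,
            })
        for col, lab in _CONTINUOUS_SUMMARY:
            vals = sub[col].dropna().astype(float)
            if len(vals) == 0:
                med = q1 = q3 = np.nan
            else:
                q1, med, q3 = np.percentile(vals, [25, 50, 75])
            out.append({
                "variable": col, "level": "median (i.q.r.)", "group": level,
                "n": int(sub[col].notna().sum()), "denominator": len(sub),
                "percent": np.nan, "median": med, "q1": q1, "q3": q3,
            })
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# result serialisation


def results_to_frame(results) -> pd.DataFrame:
    """Flatten BenchmarkResult objects (or pass a DataFrame through)."""
    if isinstance(results, pd.DataFrame):
        return results.copy()
    rows = []
    for r in results:
        rows.append({
            "outcome": r.outcome, "method": r.method,
            "benchmark_value": r.benchmark_value,
            "p25": r.p25, "p50": r.p50, "p75": r.p75,
            "n_centres": r.n_centres,
            "selected_centres": ";".join(r.selected_centres or []),
            "selected_n": r.selected_n, "pool_n": r.pool_n,
        })
    return pd.DataFrame(rows)


def write_results(results, path: str | Path, format: str = "csv") -> None:
    """Write a result table; CSV or JSON (one object per outcome, keyed by name)."""
    path = Path(path)
    if not path.parent.exists():
        raise RegistryError(f"parent directory does not exist: {path.parent}")
    frame = results_to_frame(results)
    if format == "csv":
        frame.to_csv(path, index=False)
    elif format == "json":
        payload = {
            row["outcome"]: {k: v for k, v in row.items() if k != "outcome"}
            for row in frame.replace({np.nan: None}).to_dict("records")
        } if "outcome" in frame.columns else frame.replace({np.nan: None}).to_dict("records")
        path.write_text(json.dumps(payload, indent=2, default=float) + "\n")
    else:
        raise ValueError(f"unknown format {format!r}")


def read_results(path: str | Path, format: str = "csv") -> pd.DataFrame:
    path = Path(path)
    if format == "csv":
        return pd.read_csv(path)
    if format == "json":
        payload = json.loads(path.read_text())
        if isinstance(payload, dict):
            rows = [{"outcome": k, **v} for k, v in payload.items()]
            return pd.DataFrame(rows)
        return pd.DataFrame(payload)
    raise ValueError(f"unknown format {format!r}")
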