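"""The ten benchmark outcomes.

Each outcome is declared once as an :class:`OutcomeSpec` mapping the registry
columns to a per-patient event flag (binary outcomes) or numeric value
(continuous outcomes), with MISSING propagated. All ten are lower-is-better.

The zero-event exclusion flag marks the four outcomes (overall morbidity,
major morbidity, conversion, clinically relevant POPF) for which a centre
reporting zero events is dropped before the ABC ranking: a zero rate for
these is not considered achievable in practice, so an all-zero centre is
read as under-reporting rather than top performance. Failure to preserve
the spleen, readmission and mortality keep their zero-event centres — a
true zero is attainable there.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Literal

import pandas as pd

from . import schema


@dataclass(frozen=True)
class OutcomeSpec:
    name: str
    label: str
    kind: Literal["binary", "continuous"]
    extractor: Callable[[pd.DataFrame], pd.Series] = field(repr=False)
    unit: str = "%"
    zero_event_exclusion: bool = False
    # every outcome is lower-is-better; kept explicit for the interpretation
    # contract of benchmark cut-offs
    direction: Literal["lower"] = "lower"

    def extract(self, df: pd.DataFrame) -> pd.Series:
        """Per-patient values (boolean or Float64 series), MISSING as pd.NA."""
        values = self.extractor(df)
        expected = "boolean" if self.kind == "binary" else "Float64"
        return values.astype(expected)


def _col(name: str) -> Callable[[pd.DataFrame], pd.Series]:
    return lambda df: df[name]


OUTCOME_SPECS: tuple[OutcomeSpec, ...] = (
    OutcomeSpec(
        "op_duration", "Duration of operation (min)", "continuous",
        _col("op_duration_min"), unit="min",
    ),
    OutcomeSpec(
        "blood_loss", "Intraoperative blood loss (ml)", "continuous",
        _col("blood_loss_ml"), unit="ml",
    ),
    OutcomeSpec(
        "conversion", "Conversion (%)", "binary",
        _col("conversion"), zero_event_exclusion=True,
    ),
    OutcomeSpec(
        "spleen_preservation_failure", "Failure to preserve spleen (%)",
        "binary", _col("spleen_preservation_failed"),
    ),
    OutcomeSpec(
        "overall_morbidity", "Overall morbidity (%)", "binary",
        lambda df: schema.cd_at_least(df["clavien_dindo"], "I"),
        zero_event_exclusion=True,
    ),
    OutcomeSpec(
        "major_morbidity", "Major morbidity (%)", "binary",
        lambda df: schema.cd_at_least(df["clavien_dindo"], "IIIa"),
        zero_event_exclusion=True,
    ),
    OutcomeSpec(
        "cr_popf", "CR-POPF (%)", "binary",
        lambda df: df["popf_grade"].isin(["B", "C"]).mask(
            df["popf_grade"].isna()).astype("boolean"),
        zero_event_exclusion=True,
    ),
    OutcomeSpec(
        "hospital_stay", "Duration of hospital stay (days)", "continuous",
        _col("los_days"), unit="days",
    ),
    OutcomeSpec(
        "readmission", "Readmission within 90 days (%)", "binary",
        _col("readmission_90d"),
    ),
    OutcomeSpec(
        "mortality", "90-day mortality (%)", "binary",
        _col("mortality_90d"),
    ),
)

OUTCOMES_BY_NAME = {s.name: s for s in OUTCOME_SPECS}
BINARY_OUTCOMES = tuple(s for s in OUTCOME_SPECS if s.kind == "binary")
CONTINUOUS_OUTCOMES = tuple(s for s in OUTCOME_SPECS if s.kind == "continuous")


def get_outcome(name: str) -> OutcomeSpec:
    try:
        return OUTCOMES_BY_NAME[name]
    except KeyError:
        raise KeyError(
            f"unknown outcome {name!r}; expected one of "
            f"{sorted(OUTCOMES_BY_NAME)}"
        ) from None
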