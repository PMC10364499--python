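"""Best-patient-in-best-centre (BPBC) benchmark cut-offs.

Centre-level outcome values — the median for continuous outcomes, the event
proportion for binary ones (the proportion is the natural centre-level
analogue of a median for a flag) — are computed on the low-risk cohort in
volume-eligible centres, one value per centre, and the benchmark cut-off is
the 75th percentile of those values across centres (unweighted: one centre,
one vote). Values at or below the cut-off are within benchmark for these
lower-is-better outcomes; the 25th percentile is reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .abc_benchmark import BenchmarkResult
from .cohort_filters import AttritionReport, apply_low_risk_cohort
from .outcomes import OUTCOME_SPECS, OutcomeSpec
from .registry import RegistryTable, extract_outcome


@dataclass(frozen=True)
class CentreValue:
    centre_id: str
    n: int
    value: float  # centre median (continuous) or event proportion (binary)

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("centre value requires n >= 1")


def centre_level_values(low_risk: RegistryTable, spec: OutcomeSpec,
                        stratum: str = "all") -> list[CentreValue]:
    """One CentreValue per centre with >= 1 non-missing outcome in the stratum."""
    sub = low_risk.stratum(stratum)
    vals = extract_outcome(sub, spec)
    keep = vals.notna() & sub.df["centre_id"].notna()
    df = pd.DataFrame({"centre": sub.df["centre_id"][keep],
                       "value": vals[keep].astype(float)})
    out = []
    for centre, grp in df.groupby("centre", observed=True):
        v = grp["value"].to_numpy()
        value = float(v.mean()) if spec.kind == "binary" else float(np.median(v))
        out.append(CentreValue(centre_id=str(centre), n=len(v), value=value))
    return out


def bpbc_cutoffs(values: list[CentreValue], outcome: str = "",
                 scale_percent: bool = False) -> BenchmarkResult:
    """75th percentile of centre values as the benchmark cut-off.

    Percentiles are linear-interpolated across centres (same convention as
    the ABC module). Binary outcomes are reported in percent.
    """
    if not values:
        raise ValueError("need at least one centre value")
    arr = np.array([v.value for v in values], dtype=float)
    p25, p50, p75 = np.percentile(arr, [25, 50, 75])
    scale = 100.0 if scale_percent else 1.0
    return BenchmarkResult(
        outcome=outcome, method="BPBC",
        benchmark_value=float(p75) * scale,
        p25=float(p25) * scale, p50=float(p50) * scale, p75=float(p75) * scale,
        n_centres=len(values),
        pool_n=int(sum(v.n for v in values)),
    )


def run_bpbc_suite(table: RegistryTable, stratum: str = "all",
                   min_annual: float = 10, volume_rule: str = "mean",
                   ) -> tuple[dict[str, BenchmarkResult], AttritionReport]:
    """BPBC cut-offs for all ten outcomes on one approach stratum.

    Chains the low-risk cohort filter (patient eligibility + centre volume)
    with the centre-level aggregation and the 75th-percentile cut-off.
    """
    low_risk, attrition = apply_low_risk_cohort(
        table, min_annual=min_annual, volume_rule=volume_rule)
    if len(low_risk) == 0:
        raise ValueError("low-risk cohort is empty; no BPBC benchmark can be "
                         "computed")
    results: dict[str, BenchmarkResult] = {}
    for spec in OUTCOME_SPECS:
        values = centre_level_values(low_risk, spec, stratum=stratum)
        if not values:
            results[spec.name] = BenchmarkResult(
                outcome=spec.name, method="BPBC", benchmark_value=None,
                note="no centre has a non-missing value in this stratum")
            continue
        results[spec.name] = bpbc_cutoffs(
            values, outcome=spec.name, scale_percent=(spec.kind == "binary"))
    return results, attrition
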