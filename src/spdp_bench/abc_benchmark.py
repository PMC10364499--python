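"""Achievable Benchmark of Care (ABC) on the unselected cohort.

For a binary outcome the ABC is the pooled event rate of the best-performing
centres. Centres are ranked by their *adjusted performance fraction*

    (events + 1) / (patients + 2),

which shrinks small-centre rates toward 1/2 so a centre with 0/2 cannot
outrank the field on noise alone, and the shortest prefix of the ranking
whose patients sum to at least 10% of the outcome's patient pool is pooled
(extended through exact ties in adjusted fraction at the cut).
For the four outcomes where a zero event rate is not considered achievable
in practice (overall morbidity, major morbidity, conversion, CR-POPF),
centres with zero events are dropped before ranking.

For a continuous outcome the mechanism is replaced wholesale: the ABC is the
10th percentile of the per-centre medians. All percentiles use linear
interpolation between order statistics (numpy's default, Hyndman-Fan type 7).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .outcomes import OUTCOME_SPECS, OutcomeSpec
from .registry import RegistryTable, extract_outcome


class NoEstimableCentresError(ValueError):
    """Every centre was excluded by the zero-event rule."""


@dataclass(frozen=True)
class CentreSummary:
    """Per-centre outcome summary entering the ABC ranking."""

    centre_id: str
    n: int
    events: int | None = None          # binary outcomes only
    crude_value: float = float("nan")  # events/n, or centre median
    adjusted_fraction: float | None = None

    def __post_init__(self) -> None:
        if self.events is not None and not (0 <= self.events <= self.n):
            raise ValueError(f"events must lie in [0, n]: {self}")


@dataclass
class BenchmarkResult:
    outcome: str
    method: str                     # "ABC" or "BPBC"
    benchmark_value: float | None   # % for binary, outcome units otherwise
    p25: float | None = None
    p50: float | None = None
    p75: float | None = None
    n_centres: int = 0
    selected_centres: list[str] = field(default_factory=list)
    pool_n: int = 0
    selected_n: int = 0
    note: str = ""

    @property
    def estimable(self) -> bool:
        return self.benchmark_value is not None


def adjusted_fraction(events: int, n: int) -> float:
    """(events + 1) / (n + 2): the shrunken centre event rate in (0, 1).

    Equals the n/(n+2)-weighted average of the crude rate events/n and 1/2,
    so it always lies weakly between the crude rate and one half.
    """
    if events < 0 or n < 0 or events > n:
        raise ValueError(f"need 0 <= events <= n, got events={events}, n={n}")
    return (events + 1) / (n + 2)


def binary_centre_summaries(events: pd.Series, centres: pd.Series) -> list[CentreSummary]:
    """Aggregate per-patient event flags (MISSING dropped) by centre."""
    keep = events.notna() & centres.notna()
    df = pd.DataFrame({"centre": centres[keep], "event": events[keep].astype(bool)})
    out = []
    for centre, grp in df.groupby("centre", observed=True):
        n = len(grp)
        e = int(grp["event"].sum())
        out.append(CentreSummary(
            centre_id=str(centre), n=n, events=e, crude_value=e / n,
            adjusted_fraction=adjusted_fraction(e, n)))
    return out


def _rank_key(s: CentreSummary) -> tuple:
    # ascending adjusted fraction; ties: larger n first (more evidence of
    # good performance), then centre_id for determinism
    return (s.adjusted_fraction, -s.n, s.centre_id)


def abc_binary(summaries: list[CentreSummary], pool_fraction: float = 0.10,
               exclude_zero_event: bool = False,
               pool_basis: str = "post_exclusion") -> BenchmarkResult:
    """ABC for one binary outcome from per-centre summaries.

    pool_basis controls the denominator of the 10% accumulation threshold:
    'post_exclusion' (default) uses the pool remaining after the zero-event
    exclusion, 'pre_exclusion' the full pool.
    """
    if not summaries:
        raise ValueError("need at least one centre summary")
    if not (0 < pool_fraction <= 1):
        raise ValueError("pool_fraction must lie in (0, 1]")
    total_pre = sum(s.n for s in summaries)
    ranked = list(summaries)
    if exclude_zero_event:
        ranked = [s for s in ranked if s.events > 0]
        if not ranked:
            raise NoEstimableCentresError(
                "no estimable centres: every centre has zero events for an "
                "outcome under the zero-event exclusion rule")
    ranked.sort(key=_rank_key)

    pool_total = sum(s.n for s in ranked) if pool_basis == "post_exclusion" else total_pre
    if pool_basis not in ("post_exclusion", "pre_exclusion"):
        raise ValueError(f"unknown pool_basis {pool_basis!r}")
    threshold = pool_fraction * pool_total

    # shortest prefix reaching the threshold, extended through any centres
    # tied with the last selected one on adjusted fraction: a tie carries no
    # ranking information, and including the whole tied group makes the
    # selection invariant to duplicating every centre
    prefix: list[CentreSummary] = []
    acc = 0
    stop_at = len(ranked)
    for i, s in enumerate(ranked):
        acc += s.n
        if acc >= threshold:
            stop_at = i
            break
    while stop_at + 1 < len(ranked) and (
            ranked[stop_at + 1].adjusted_fraction
            == ranked[stop_at].adjusted_fraction):
        stop_at += 1
    prefix = ranked[:stop_at + 1]
    sel_events = sum(s.events for s in prefix)
    sel_n = sum(s.n for s in prefix)
    crude = np.array([s.crude_value for s in ranked])
    p25, p50, p75 = np.percentile(crude, [25, 50, 75])
    return BenchmarkResult(
        outcome="", method="ABC",
        benchmark_value=100.0 * sel_events / sel_n,
        p25=100.0 * p25, p50=100.0 * p50, p75=100.0 * p75,
        n_centres=len(ranked),
        selected_centres=[s.centre_id for s in prefix],
        pool_n=pool_total, selected_n=sel_n,
    )


def abc_continuous(values_by_centre: dict[str, np.ndarray]) -> BenchmarkResult:
    """ABC for a continuous outcome: 10th percentile of the centre medians."""
    if not values_by_centre:
        raise ValueError("need at least one centre")
    medians = {}
    for centre, vals in values_by_centre.items():
        vals = np.asarray(vals, dtype=float)
        vals = vals[~np.isnan(vals)]
        if len(vals) == 0:
            raise ValueError(f"centre {centre!r} has no non-missing values")
        medians[centre] = float(np.median(vals))
    med = np.array(list(medians.values()))
    p10, p25, p50, p75 = np.percentile(med, [10, 25, 50, 75])
    return BenchmarkResult(
        outcome="", method="ABC", benchmark_value=float(p10),
        p25=float(p25), p50=float(p50), p75=float(p75),
        n_centres=len(med),
        pool_n=int(sum(len(np.asarray(v)[~np.isnan(np.asarray(v, dtype=float))])
                       for v in values_by_centre.values())),
    )


def values_by_centre(values: pd.Series, centres: pd.Series) -> dict[str, np.ndarray]:
    keep = values.notna() & centres.notna()
    df = pd.DataFrame({"centre": centres[keep], "value": values[keep].astype(float)})
    return {str(c): g["value"].to_numpy()
            for c, g in df.groupby("centre", observed=True)}


def run_abc_suite(table: RegistryTable, stratum: str = "all",
                  pool_fraction: float = 0.10,
                  pool_basis: str = "post_exclusion",
                  ) -> dict[str, BenchmarkResult]:
    """ABC for all ten outcomes on one approach stratum.

    An outcome whose every centre is dropped by the zero-event exclusion is
    reported as non-estimable (benchmark_value None) so the remaining
    outcomes still compute.
    """
    sub = table.stratum(stratum)
    if len(sub) == 0:
        raise ValueError(f"stratum {stratum!r} has no records")
    results: dict[str, BenchmarkResult] = {}
    for spec in OUTCOME_SPECS:
        vals = extract_outcome(sub, spec)
        if spec.kind == "binary":
            summaries = binary_centre_summaries(vals, sub.df["centre_id"])
            try:
                res = abc_binary(summaries, pool_fraction=pool_fraction,
                                 exclude_zero_event=spec.zero_event_exclusion,
                                 pool_basis=pool_basis)
            except NoEstimableCentresError as err:
                res = BenchmarkResult(outcome=spec.name, method="ABC",
                                      benchmark_value=None, note=str(err),
                                      pool_n=int(vals.notna().sum()))
        else:
            res = abc_continuous(values_by_centre(vals, sub.df["centre_id"]))
        res.outcome = spec.name
        results[spec.name] = res
    return results
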