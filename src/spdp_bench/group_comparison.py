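"""Between-approach statistical comparisons for the cohort tables.

Routing follows standard practice for clinical baseline tables: categorical
variables get an uncorrected Pearson chi-squared test unless any expected
cell count falls below 5, in which case Fisher's exact test is used;
continuous variables get a two-sided Mann-Whitney U test (exact for small
samples, tie-corrected normal approximation otherwise). Normality screening
uses the Kolmogorov-Smirnov test with the Lilliefors correction, since the
normal parameters are estimated from the sample.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.diagnostic import lilliefors

from . import schema
from .registry import RegistryTable, _categorical_rows, _CONTINUOUS_SUMMARY

EXACT_MW_MAX_N = 20  # per group; above this the normal approximation is used


@dataclass
class ComparisonRow:
    variable: str
    level: str
    kind: str                 # "categorical" | "continuous"
    group_summaries: dict[str, str]
    test: str                 # "chi_square" | "fisher" | "mann_whitney"
    p_value: float
    significant: bool         # two-sided P < 0.050

    def formatted_p(self) -> str:
        if self.p_value < 0.001:
            return "<0.001"
        return f"{self.p_value:.3f}"


def pearson_chisq(table2x2) -> tuple[float, float, str]:
    """Uncorrected Pearson chi-squared on a 2x2 table.

    Returns (statistic, two-sided p, test_used). A table with a zero margin
    has no chi-squared sampling distribution and is routed to Fisher's exact
    test (statistic reported as NaN).
    """
    t = np.asarray(table2x2, dtype=float).reshape(2, 2)
    if (t < 0).any():
        raise ValueError("counts must be non-negative")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        return float("nan"), fisher_exact(t), "fisher"
    stat, p, _, _ = stats.chi2_contingency(t, correction=False)
    return float(stat), float(p), "chi_square"


def fisher_exact(table2x2) -> float:
    """Two-sided Fisher exact p: sum of hypergeometric probabilities of all
    tables (fixed margins) no more probable than the observed one."""
    t = np.asarray(table2x2, dtype=int).reshape(2, 2)
    return float(stats.fisher_exact(t, alternative="two-sided")[1])


def mann_whitney(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U.

    Exact null distribution when both groups have at most 20 observations and
    there are no cross-sample ties; the tie-corrected normal approximation
    otherwise. Returns (U for x, two-sided p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        warnings.warn("all values tied across both samples; p = 1")
        return len(x) * len(y) / 2.0, 1.0
    has_ties = len(np.unique(pooled)) < len(pooled)
    if len(x) <= EXACT_MW_MAX_N and len(y) <= EXACT_MW_MAX_N and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def ks_normality(x, alpha: float = 0.05) -> str:
    """Kolmogorov-Smirnov normality screen with Lilliefors correction.

    Returns 'normal' or 'skewed'; routes presentation to mean vs
    median (i.q.r.). Degenerate (constant) samples are labelled skewed.
    """
    x = np.asarray(x, dtype=float)
    x = x[~np.isnan(x)]
    if len(x) < 5:
        raise ValueError("need at least 5 observations")
    if np.all(x == x[0]):
        warnings.warn("constant sample; reporting as skewed")
        return "skewed"
    _, p = lilliefors(x, dist="norm")
    return "normal" if p >= alpha else "skewed"


def _route_categorical(table2x2) -> tuple[float, str]:
    """Chi-squared unless any expected count < 5, then Fisher."""
    t = np.asarray(table2x2, dtype=float).reshape(2, 2)
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        return fisher_exact(t), "fisher"
    expected = np.outer(t.sum(axis=1), t.sum(axis=0)) / t.sum()
    if (expected < 5).any():
        return fisher_exact(t), "fisher"
    _, p, test = pearson_chisq(t)
    return p, test


def compare_groups(table: RegistryTable, cohort: str = "unselected",
                   alpha: float = 0.05) -> list[ComparisonRow]:
    """Laparoscopic-vs-robotic comparison table for a registry.

    cohort is a label recorded for provenance ('unselected' or 'low_risk');
    the caller passes the corresponding table. Rows with an entirely missing
    variable in either group are omitted with a warning.
    """
    df = table.df
    groups = {
        a: df[(df["approach"] == a).fillna(False)] for a in schema.APPROACHES
    }
    if any(len(g) == 0 for g in groups.values()):
        raise ValueError("both approach groups must be non-empty")

    rows: list[ComparisonRow] = []
    flag_rows = {a: _categorical_rows(g) for a, g in groups.items()}
    for idx, (var, level, _) in enumerate(flag_rows["laparoscopic"]):
        if var == "spleen_preserved":
            continue  # complement of spleen_preservation_failed; no second test
        counts = {}
        ok = True
        for a in schema.APPROACHES:
            flag = flag_rows[a][idx][2]
            denom = int(flag.notna().sum())
            if denom == 0:
                warnings.warn(f"{var} entirely missing in {a} group; row omitted")
                ok = False
                break
            counts[a] = (int(flag.fillna(False).sum()), denom)
        if not ok:
            continue
        t = [[counts[a][0], counts[a][1] - counts[a][0]] for a in schema.APPROACHES]
        p, test = _route_categorical(t)
        rows.append(ComparisonRow(
            variable=var, level=level, kind="categorical",
            group_summaries={
                a: f"{counts[a][0]} ({100 * counts[a][0] / counts[a][1]:.1f})"
                for a in schema.APPROACHES},
            test=test, p_value=p, significant=p < alpha))

    for col, label in _CONTINUOUS_SUMMARY:
        samples = {}
        ok = True
        for a in schema.APPROACHES:
            v = groups[a][col].dropna().astype(float).to_numpy()
            if len(v) == 0:
                warnings.warn(f"{col} entirely missing in {a} group; row omitted")
                ok = False
                break
            samples[a] = v
        if not ok:
            continue
        _, p = mann_whitney(samples["laparoscopic"], samples["robotic"])
        summaries = {}
        for a, v in samples.items():
            q1, med, q3 = np.percentile(v, [25, 50, 75])
            summaries[a] = f"{med:g} ({q1:g}-{q3:g})"
        rows.append(ComparisonRow(
            variable=col, level="median (i.q.r.)", kind="continuous",
            group_summaries=summaries, test="mann_whitney",
            p_value=p, significant=p < alpha))
    return rows


def comparison_frame(rows: list[ComparisonRow]) -> pd.DataFrame:
    return pd.DataFrame([
        {"variable": r.variable, "level": r.level, "kind": r.kind,
         **{f"group_{a}": r.group_summaries.get(a) for a in schema.APPROACHES},
         "test": r.test, "p_value": r.p_value, "p": r.formatted_p(),
         "significant": r.significant}
        for r in rows
    ])
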