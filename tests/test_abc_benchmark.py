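import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from spdp_bench.abc_benchmark import (BenchmarkResult, CentreSummary,
                                      NoEstimableCentresError, abc_binary,
                                      abc_continuous, adjusted_fraction,
                                      binary_centre_summaries, run_abc_suite)
from spdp_bench.outcomes import OUTCOME_SPECS
from spdp_bench.registry import extract_outcome
from spdp_bench.synthetic_registry import generate_registry

from conftest import make_rows, make_table, small_config


def centres(*pairs):
    return [
        CentreSummary(centre_id=f"c{i}", n=n, events=e, crude_value=e / n,
                      adjusted_fraction=adjusted_fraction(e, n))
        for i, (e, n) in enumerate(pairs)
    ]


# ---------------------------------------------------------------------------
# adjusted performance fraction


def test_adjusted_fraction_values():
    assert adjusted_fraction(0, 0) == 0.5
    assert adjusted_fraction(2, 40) == pytest.approx(3 / 42)
    assert adjusted_fraction(40, 40) == pytest.approx(41 / 42)


def test_adjusted_fraction_rejects_bad_input():
    for e, n in [(-1, 5), (6, 5), (1, -1)]:
        with pytest.raises(ValueError):
            adjusted_fraction(e, n)


def test_shrinkage_identity_full_grid():
    """(e+1)/(n+2) is the n/(n+2)-weighted mean of e/n and 1/2, for all
    0 <= e <= n <= 200."""
    for n in range(0, 201):
        for e in range(0, n + 1):
            af = adjusted_fraction(e, n)
            if n > 0:
                expected = (n / (n + 2)) * (e / n) + (2 / (n + 2)) * 0.5
                assert af == pytest.approx(expected, abs=1e-12)
                assert min(e / n, 0.5) - 1e-12 <= af <= max(e / n, 0.5) + 1e-12
            assert 0 < af < 1


# ---------------------------------------------------------------------------
# binary ABC


def brute_force_abc(summaries, pool_fraction=0.10, exclude_zero_event=False):
    """Independent oracle: explicit sort + explicit prefix enumeration.

    Enumerates every prefix of the ranking, keeps the first one reaching the
    patient threshold, then widens it while the next centre has exactly the
    same adjusted fraction as the prefix's last member."""
    cand = [s for s in summaries if not (exclude_zero_event and s.events == 0)]
    if not cand:
        return None
    ranked = sorted(cand, key=lambda s: ((s.events + 1) / (s.n + 2), -s.n,
                                         s.centre_id))
    need = pool_fraction * sum(s.n for s in ranked)
    best = None
    for k in range(1, len(ranked) + 1):
        prefix = ranked[:k]
        if sum(s.n for s in prefix) >= need:
            best = prefix
            break
    if best is None:
        best = ranked
    k = len(best)
    while k < len(ranked) and ((ranked[k].events + 1) / (ranked[k].n + 2)
                               == (best[-1].events + 1) / (best[-1].n + 2)):
        best = ranked[:k + 1]
        k += 1
    return 100.0 * sum(s.events for s in best) / sum(s.n for s in best), [
        s.centre_id for s in best]


def test_single_centre():
    res = abc_binary(centres((5, 100)))
    assert res.benchmark_value == pytest.approx(5.0)
    assert res.selected_centres == ["c0"]


def test_spec_three_centre_example_without_exclusion():
    # A: 0/30 (adj 1/32), B: 2/40 (adj 3/42), C: 10/30 (adj 11/32)
    res = abc_binary(centres((0, 30), (2, 40), (10, 30)))
    assert res.selected_centres == ["c0"]
    assert res.benchmark_value == 0.0


def test_spec_three_centre_example_with_exclusion():
    res = abc_binary(centres((0, 30), (2, 40), (10, 30)),
                     exclude_zero_event=True)
    assert res.selected_centres == ["c1"]  # A dropped; B alone covers 40/70
    assert res.benchmark_value == pytest.approx(5.0)


def test_all_zero_event_centres_error():
    with pytest.raises(NoEstimableCentresError):
        abc_binary(centres((0, 10), (0, 20)), exclude_zero_event=True)


def test_zero_floor_when_zero_event_centres_admitted():
    res = abc_binary(centres((0, 30), (0, 25), (5, 10)))
    assert res.benchmark_value == 0.0


def test_pool_fraction_one_pools_everything():
    summ = centres((1, 10), (2, 20), (3, 30))
    res = abc_binary(summ, pool_fraction=1.0)
    assert res.selected_n == 60
    assert res.benchmark_value == pytest.approx(100 * 6 / 60)


def test_oracle_equivalence_randomized(rng):
    """abc_binary agrees with the brute-force prefix oracle on 1000 random
    instances of up to 6 centres with up to 20 patients each."""
    for _ in range(1000):
        k = rng.integers(1, 7)
        ns = rng.integers(1, 21, size=k)
        es = np.array([rng.integers(0, n + 1) for n in ns])
        summ = centres(*zip(es, ns))
        excl = bool(rng.random() < 0.5)
        oracle = brute_force_abc(summ, exclude_zero_event=excl)
        if oracle is None:
            with pytest.raises(NoEstimableCentresError):
                abc_binary(summ, exclude_zero_event=excl)
            continue
        res = abc_binary(summ, exclude_zero_event=excl)
        assert res.benchmark_value == pytest.approx(oracle[0])
        assert res.selected_centres == oracle[1]


def test_prefix_minimality(rng):
    """Dropping the whole tied group at the cut puts the prefix below the
    10% bar (with no ties this is just the last-selected centre)."""
    for _ in range(200):
        k = rng.integers(2, 8)
        ns = rng.integers(1, 40, size=k)
        es = np.array([rng.integers(0, n + 1) for n in ns])
        summ = centres(*zip(es, ns))
        res = abc_binary(summ)
        by_id = {s.centre_id: s for s in summ}
        selected = [by_id[c] for c in res.selected_centres]
        if len(selected) > 1:
            cut_af = selected[-1].adjusted_fraction
            kept = sum(s.n for s in selected if s.adjusted_fraction != cut_af)
            assert kept < 0.10 * res.pool_n


def test_permutation_invariance(rng):
    summ = centres((1, 12), (0, 9), (4, 18), (2, 30), (7, 21))
    base = abc_binary(summ)
    for _ in range(20):
        perm = list(rng.permutation(len(summ)))
        res = abc_binary([summ[i] for i in perm])
        assert res.benchmark_value == base.benchmark_value
        assert sorted(res.selected_centres) == sorted(base.selected_centres)
        assert (res.p25, res.p50, res.p75) == (base.p25, base.p50, base.p75)


def test_clone_invariance_randomized(rng):
    """Duplicating every centre leaves the binary ABC value unchanged and the
    selected prefix consists of the original prefix's duplicate pairs."""
    for _ in range(300):
        k = int(rng.integers(1, 7))
        ns = rng.integers(1, 25, size=k)
        es = np.array([rng.integers(0, n + 1) for n in ns])
        summ = centres(*zip(es, ns))
        clones = summ + [
            CentreSummary(centre_id=s.centre_id + "x", n=s.n, events=s.events,
                          crude_value=s.crude_value,
                          adjusted_fraction=s.adjusted_fraction)
            for s in summ
        ]
        base = abc_binary(summ)
        doubled = abc_binary(clones)
        assert doubled.benchmark_value == pytest.approx(base.benchmark_value)
        assert {c.rstrip("x") for c in doubled.selected_centres} == set(
            base.selected_centres)


def test_tie_break_prefers_larger_centre():
    # equal adjusted fractions 2/20 -> (3/22); 20 patients beats a clone order
    a = CentreSummary("small", 20, 2, 0.1, adjusted_fraction(2, 20))
    b = CentreSummary("big", 64, 8, 0.125, adjusted_fraction(8, 64))
    assert adjusted_fraction(2, 20) == pytest.approx(adjusted_fraction(8, 64))
    res = abc_binary([a, b], pool_fraction=0.10)
    assert res.selected_centres[0] == "big"


# ---------------------------------------------------------------------------
# continuous ABC


def test_continuous_constant_medians():
    res = abc_continuous({f"c{i}": [7.0, 7.0] for i in range(5)})
    assert res.benchmark_value == 7.0


def test_continuous_linear_interpolation():
    med = {f"c{i}": [float(v)] for i, v in enumerate(range(5, 15))}
    res = abc_continuous(med)
    assert res.benchmark_value == pytest.approx(5.9)


def test_continuous_single_centre():
    res = abc_continuous({"only": [4.0, 8.0, 6.0]})
    assert res.benchmark_value == 6.0


def test_continuous_rejects_empty():
    with pytest.raises(ValueError):
        abc_continuous({})


# ---------------------------------------------------------------------------
# suite


def test_suite_selected_n_meets_pool_threshold():
    table, _ = generate_registry(small_config(seed=11, n_centres=10,
                                              volume_mean=30.0))
    results = run_abc_suite(table, stratum="laparoscopic")
    assert set(results) == {s.name for s in OUTCOME_SPECS}
    for spec in OUTCOME_SPECS:
        res = results[spec.name]
        if spec.kind == "binary" and res.estimable:
            assert res.selected_n >= math.ceil(0.10 * res.pool_n) - 1e-9


def test_suite_no_conversion_events_marks_only_conversion():
    rows = make_rows(30, centre_id=[f"C{i % 3}" for i in range(30)],
                     clavien_dindo=[["0", "II", "IIIa"][i % 3] for i in range(30)],
                     popf_grade=[["none", "B"][i % 2] for i in range(30)])
    table = make_table(rows)
    results = run_abc_suite(table, stratum="all")
    assert not results["conversion"].estimable
    assert "no estimable centres" in results["conversion"].note
    assert results["overall_morbidity"].estimable
    assert results["cr_popf"].estimable


def test_suite_clone_invariance():
    table, _ = generate_registry(small_config(seed=5))
    df = table.df.copy()
    clone = df.copy()
    clone["patient_id"] = "dup_" + clone["patient_id"].astype(str)
    clone["centre_id"] = "dup_" + clone["centre_id"].astype(str)
    import pandas as pd

    from spdp_bench import registry as reg
    doubled = reg.RegistryTable(pd.concat([df, clone], ignore_index=True),
                                provenance="doubled")
    r1 = run_abc_suite(table)
    r2 = run_abc_suite(doubled)
    for spec in OUTCOME_SPECS:
        a, b = r1[spec.name], r2[spec.name]
        if not a.estimable:
            continue
        if spec.kind == "binary":
            assert b.benchmark_value == pytest.approx(a.benchmark_value)
        else:
            # the 10th percentile of medians under duplication moves by at
            # most one gap between adjacent centre medians
            from spdp_bench.abc_benchmark import values_by_centre
            vals = extract_outcome(table, spec)
            medians = np.sort([np.median(v) for v in values_by_centre(
                vals, table.df["centre_id"]).values()])
            gap = np.max(np.diff(medians)) if len(medians) > 1 else 0.0
            assert abs(b.benchmark_value - a.benchmark_value) <= gap + 1e-9


def test_binary_centre_summaries_drop_missing():
    import pandas as pd
    events = pd.Series([True, False, pd.NA, True], dtype="boolean")
    cents = pd.Series(["a", "a", "a", "b"], dtype="string")
    summ = binary_centre_summaries(events, cents)
    by_id = {s.centre_id: s for s in summ}
    assert by_id["a"].n == 2 and by_id["a"].events == 1
    assert by_id["b"].n == 1
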