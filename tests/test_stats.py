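"""Population statistics: summaries, histograms, pooling, test oracles."""

import math
from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats as sps

from nucleoquant import (
    compare_conditions,
    derived_columns,
    derived_summary_table,
    ks_test,
    make_histogram,
    pool_conditions,
    ranksum_test,
    summarize,
)


def lognormal_mean_cv(rng, mean, cv, n):
    s2 = math.log1p(cv * cv)
    return rng.lognormal(math.log(mean) - s2 / 2, math.sqrt(s2), n)


def records_from(values, channel="protein"):
    return pd.DataFrame({f"mean_{channel}": values})


# ------------------------------------------------------------------ summaries

def test_two_point_summary():
    s = summarize(records_from([0.2, 0.4]), "protein")
    assert s.mean == pytest.approx(0.3)
    assert s.sd == pytest.approx(0.1414, abs=1e-4)
    assert s.n == 2


def test_single_value_summary_is_degenerate(caplog):
    with caplog.at_level("WARNING", logger="nucleoquant"):
        s = summarize(records_from([0.5]), "protein")
    assert (s.mean, s.sd, s.n) == (0.5, 0.0, 1)
    assert any("degenerate" in r.message for r in caplog.records)


def test_summary_recovers_configured_mean():
    rng = np.random.default_rng(21)
    s = summarize(records_from(lognormal_mean_cv(rng, 0.58, 0.3, 1000)), "protein")
    assert s.mean == pytest.approx(0.58, rel=0.03)


def test_small_population_warns(caplog):
    with caplog.at_level("WARNING", logger="nucleoquant"):
        summarize(records_from(np.linspace(0.1, 0.9, 40)), "protein")
    assert any("recommended" in r.message for r in caplog.records)


def test_empty_summary_rejected():
    with pytest.raises(ValueError):
        summarize(records_from([]), "protein")


# ----------------------------------------------------------------- histograms

def test_identical_values_fill_one_bin():
    h = make_histogram([0.4] * 7, edges=[0.0, 0.3, 0.5, 1.0])
    assert h.percent.tolist() == [0.0, 100.0, 0.0]


def test_hand_counted_histogram():
    h = make_histogram([1, 2, 3, 4], edges=[0, 2.5, 5])
    assert h.percent.tolist() == [50.0, 50.0]


def test_last_bin_is_closed():
    h = make_histogram([0.0, 1.0], edges=[0.0, 0.5, 1.0])
    assert h.percent.tolist() == [50.0, 50.0]


@given(st.lists(st.floats(0.01, 0.99), min_size=1, max_size=300))
def test_histogram_percentages_conserve_total(values):
    h = make_histogram(values, bins=13)
    assert abs(h.percent.sum() - 100.0) < 1e-9


def test_histogram_rejects_empty_and_uncovering_edges():
    with pytest.raises(ValueError):
        make_histogram([])
    with pytest.raises(ValueError):
        make_histogram([0.1, 5.0], edges=[0, 1])


# -------------------------------------------------------------------- pooling

def test_pooling_four_sources_of_1000():
    """Four per-animal tables of 1000 nuclei pool to >4000 scored nuclei."""
    rng = np.random.default_rng(3)
    tables = {f"mouse_{i}": records_from(rng.uniform(0, 1, 1000)) for i in range(4)}
    pooled = pool_conditions(tables)
    assert len(pooled) == 4000
    assert set(pooled.source.unique()) == set(tables)


def test_pooling_single_table_is_identity():
    df = records_from([0.1, 0.2, 0.3])
    out = pool_conditions([df])
    pd.testing.assert_frame_equal(out, df)


def test_pooled_mean_is_weighted_mean_of_sources():
    rng = np.random.default_rng(4)
    tabs = [records_from(rng.uniform(0, 1, n)) for n in (100, 400, 250)]
    pooled = pool_conditions(tabs)
    weighted = sum(t.mean_protein.mean() * len(t) for t in tabs) / 750
    assert pooled.mean_protein.mean() == pytest.approx(weighted)


def test_pooling_rejects_schema_mismatch():
    with pytest.raises(ValueError):
        pool_conditions([records_from([0.1]), pd.DataFrame({"other": [1]})])


# ---------------------------------------------------------------- comparisons

def test_identical_condition_has_unit_fold_changes():
    rng = np.random.default_rng(5)
    df = pd.DataFrame({
        "mean_protein": lognormal_mean_cv(rng, 0.3, 0.3, 500),
        "mean_dna": lognormal_mean_cv(rng, 0.38, 0.1, 500),
    })
    res = compare_conditions(df, df, "a", "a")
    assert res.fold_change_protein == 1.0
    assert res.fold_change_ratio == 1.0


def test_large_samples_from_shifted_distributions_are_detected():
    """Populations drawn at the two published condition means are told
    apart by all three tests at p < 0.001."""
    rng = np.random.default_rng(6)
    a = pd.DataFrame({"mean_protein": lognormal_mean_cv(rng, 0.30, 0.3, 1000),
                      "mean_dna": lognormal_mean_cv(rng, 0.38, 0.1, 1000)})
    b = pd.DataFrame({"mean_protein": lognormal_mean_cv(rng, 0.58, 0.3, 1000),
                      "mean_dna": lognormal_mean_cv(rng, 0.40, 0.1, 1000)})
    res = compare_conditions(a, b, "early", "senescent")
    assert res.fold_change_protein == pytest.approx(0.58 / 0.30, rel=0.05)
    assert res.p_ttest < 1e-3 and res.p_ks < 1e-3 and res.p_wilcoxon < 1e-3
    # oracle: the same draws through reference routines directly
    assert res.p_ks == sps.ks_2samp(a.mean_protein, b.mean_protein).pvalue


def test_zero_reference_mean_rejected():
    a = pd.DataFrame({"mean_protein": [0.0, 0.0, 0.0], "mean_dna": [1, 1, 1.0]})
    b = pd.DataFrame({"mean_protein": [0.1, 0.2, 0.3], "mean_dna": [1, 1, 1.0]})
    with pytest.raises(ZeroDivisionError):
        compare_conditions(a, b)


# ----------------------------------------------- printed-table reproduction

def test_derived_columns_follow_printed_rounding_convention():
    cells = derived_columns(0.59, 0.28, 0.36, 0.31)
    assert cells["ratio_2dp"] == 2.11
    # full precision rounds to 1.81; the printed table divides 2-dp ratios
    assert round(cells["fold_ratio"], 2) == 1.81
    assert cells["fold_ratio_2dp"] == 1.82


def test_summary_table_reference_rows_are_unity():
    table = derived_summary_table(
        [("early", 0.30, 0.38), ("senescent", 0.58, 0.40)], reference="early")
    ref = table[table.condition == "early"].iloc[0]
    assert ref.fold_protein == 1.0 and ref.fold_ratio == 1.0


# ------------------------------------------------------- brute-force oracles

def u_stat_brute(a, b):
    return sum(1.0 if x > y else 0.5 if x == y else 0.0 for x in a for y in b)


def ks_stat_brute(a, b):
    pts = np.union1d(a, b)
    fa = np.searchsorted(np.sort(a), pts, "right") / len(a)
    fb = np.searchsorted(np.sort(b), pts, "right") / len(b)
    return np.max(np.abs(fa - fb))


def ranksum_p_normal(a, b):
    n1, n2 = len(a), len(b)
    u = u_stat_brute(a, b)
    mu = n1 * n2 / 2
    pooled = np.concatenate([a, b])
    _, counts = np.unique(pooled, return_counts=True)
    tie = float((counts**3 - counts).sum())
    big_n = n1 + n2
    sd = math.sqrt(n1 * n2 / 12 * ((big_n + 1) - tie / (big_n * (big_n - 1))))
    z = (max(u, n1 * n2 - u) - mu - 0.5) / sd
    return min(1.0, 2 * sps.norm.sf(z))


def ranksum_p_exact(a, b):
    n1 = len(a)
    pooled = np.concatenate([a, b])
    u_obs = u_stat_brute(a, b)
    u_max = max(u_obs, n1 * (len(pooled) - n1) - u_obs)
    us = [
        u_stat_brute(pooled[list(ix)], np.delete(pooled, list(ix)))
        for ix in combinations(range(len(pooled)), n1)
    ]
    return min(1.0, 2 * float(np.mean(np.asarray(us) >= u_max)))


@pytest.mark.parametrize("sizes,ties", [((25, 30), False), ((21, 25), True)])
def test_large_sample_tests_agree_with_bruteforce(sizes, ties):
    rng = np.random.default_rng(sum(sizes))
    if ties:
        a = rng.integers(0, 6, sizes[0]).astype(float)
        b = rng.integers(1, 7, sizes[1]).astype(float)
    else:
        a = rng.normal(0, 1, sizes[0])
        b = rng.normal(0.4, 1, sizes[1])
    ks_s, _ = ks_test(a, b)
    assert ks_s == pytest.approx(ks_stat_brute(a, b), abs=1e-12)
    u, p = ranksum_test(a, b)
    assert u == pytest.approx(u_stat_brute(a, b), abs=1e-9)
    assert p == pytest.approx(ranksum_p_normal(a, b), rel=1e-10)


def test_small_sample_ranksum_matches_exact_enumeration():
    rng = np.random.default_rng(13)
    a = rng.normal(0, 1, 6)
    b = rng.normal(0.5, 1, 5)
    u, p = ranksum_test(a, b)
    assert u == pytest.approx(u_stat_brute(a, b), abs=1e-9)
    assert p == pytest.approx(ranksum_p_exact(a, b), rel=1e-12)
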