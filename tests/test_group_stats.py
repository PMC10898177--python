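"""Welch tests, Fisher enrichment, BH adjustment, positional summaries."""

from __future__ import annotations

import math
from math import comb

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cisplice.group_stats import (
    benjamini_hochberg,
    boxplot_summary,
    compare_groups,
    fisher_enrichment,
    pattern_enrichment,
    positional_distribution,
    welch_t,
)


def test_welch_identical_samples():
    t, df, p = welch_t([1, 2, 3], [1, 2, 3])
    assert t == 0.0 and p == 1.0


def test_welch_closed_form_hand_value():
    t, df, p = welch_t([1, 2, 3, 4], [2, 3, 4, 5])
    assert t == pytest.approx(-1.0954, abs=1e-4)
    assert df == pytest.approx(6.0, abs=1e-9)
    # p from the t CDF at |t|, df=6
    assert p == pytest.approx(2 * stats.t.sf(1.095445, 6.0), abs=1e-5)


def test_welch_antisymmetric_in_argument_order():
    a, b = [1.0, 2.5, 3.0, 7.0], [2.0, 2.0, 5.0]
    ta, dfa, pa = welch_t(a, b)
    tb, dfb, pb = welch_t(b, a)
    assert ta == pytest.approx(-tb) and pa == pytest.approx(pb) and dfa == pytest.approx(dfb)


def test_welch_degenerate_zero_variance():
    with pytest.raises(ValueError, match="degenerate"):
        welch_t([1.0, 1.0], [2.0, 2.0])


def test_welch_needs_two_values():
    with pytest.raises(ValueError):
        welch_t([1.0], [1.0, 2.0])


def test_welch_matches_scipy_on_seeded_pairs():
    rng = np.random.default_rng(5)
    for _ in range(100):
        a = rng.normal(0, 1 + rng.random(), size=rng.integers(3, 40))
        b = rng.normal(rng.random(), 1, size=rng.integers(3, 40))
        t, df, p = welch_t(a, b)
        ref = stats.ttest_ind(a, b, equal_var=False)
        assert t == pytest.approx(ref.statistic, abs=1e-9)
        assert p == pytest.approx(ref.pvalue, abs=1e-9)


def _enumerate_fisher(a, b, c, d):
    """Independent two-sided Fisher oracle by full hypergeometric enumeration."""
    r1, r2, n1 = a + b, c + d, a + c
    N = r1 + r2
    denom = comb(N, n1)
    probs = {}
    for k in range(max(0, n1 - r2), min(r1, n1) + 1):
        probs[k] = comb(r1, k) * comb(r2, n1 - k) / denom
    p_obs = probs[a]
    return sum(p for p in probs.values() if p <= p_obs * (1 + 1e-9))


def test_fisher_enumerated_example():
    # [[3,0],[0,3]]: P(0)=P(3)=1/20, P(1)=P(2)=9/20; two-sided = 0.1
    res = fisher_enrichment(3, 3, 0, 3)
    assert res.p_value == pytest.approx(0.1, abs=1e-12)
    assert math.isinf(res.odds_ratio)


def test_fisher_symmetric_table_p_one():
    res = fisher_enrichment(1, 2, 1, 2)
    assert res.p_value == pytest.approx(1.0, abs=1e-12)


def test_fisher_empty_universe_missing():
    assert fisher_enrichment(0, 0, 1, 3) is None


def test_fisher_matches_enumeration_small_tables():
    for a in range(5):
        for b in range(5):
            for c in range(5):
                for d in range(5):
                    if a + b == 0 or c + d == 0:
                        continue
                    res = fisher_enrichment(a, a + b, c, c + d)
                    assert res.p_value == pytest.approx(
                        _enumerate_fisher(a, b, c, d), abs=1e-12
                    ), (a, b, c, d)


def test_bh_step_up_hand_example():
    adj = benjamini_hochberg([0.01, 0.02, 0.9])
    assert np.allclose(adj, [0.03, 0.03, 0.9])


def test_bh_monotone_and_bounded():
    rng = np.random.default_rng(9)
    p = rng.random(200)
    adj = benjamini_hochberg(p)
    order = np.argsort(p)
    assert np.all(np.diff(adj[order]) >= -1e-12)
    assert adj.max() <= 1.0
    assert np.all(adj >= p - 1e-12)


def test_bh_passes_nan_through():
    adj = benjamini_hochberg([0.01, np.nan, 0.5])
    assert math.isnan(adj[1]) and not math.isnan(adj[0])


def _groups(**kw):
    return {k: pd.DataFrame(v) for k, v in kw.items()}


def test_compare_groups_identical_groups_all_p_one():
    data = {f"f{i}": np.arange(10.0) for i in range(5)}
    res = compare_groups(_groups(a=data, b=data), [("a", "b")], list(data))
    assert (res["p_value"] == 1.0).all()
    assert (res["p_adj"] == 1.0).all()


def test_compare_groups_single_row_bh_is_identity():
    g = _groups(a={"f": [1.0, 2, 3, 8]}, b={"f": [4.0, 5, 6, 6]})
    res = compare_groups(g, [("a", "b")], ["f"])
    assert res.loc[0, "p_adj"] == pytest.approx(res.loc[0, "p_value"])


def test_compare_groups_small_group_emits_row_without_test():
    g = _groups(a={"f": [1.0]}, b={"f": [4.0, 5, 6]})
    res = compare_groups(g, [("a", "b")], ["f"])
    assert len(res) == 1
    assert res.loc[0, "n_a"] == 1
    assert math.isnan(res.loc[0, "p_value"])
    assert res.loc[0, "mean_a"] == 1.0


def test_compare_groups_drops_missing_pairwise():
    g = _groups(
        a={"f": [1.0, np.nan, 3.0, 5.0]},
        b={"f": [2.0, 4.0, np.nan, 8.0]},
    )
    res = compare_groups(g, [("a", "b")], ["f"])
    assert res.loc[0, "n_a"] == 3 and res.loc[0, "n_b"] == 3


def test_pattern_enrichment_flags_test_and_adjusts():
    reg = {"EC": 30, "IR": 60, "ALE": 10}
    cat = {"EC": 300, "IR": 100, "ALE": 200}
    res = pattern_enrichment(reg, cat).set_index("pattern")
    assert (res["test"] == "fisher_exact_two_sided").all()
    assert res.loc["IR", "odds_ratio"] > 1
    assert (res["p_adj"] >= res["p_value"] - 1e-12).all()


def test_positional_distribution_point_mass():
    dens, mean = positional_distribution([0.5] * 8)
    assert mean == 0.5
    assert dens[5] == 1.0 and dens.sum() == pytest.approx(1.0)


def test_positional_distribution_uniform_grid():
    dens, mean = positional_distribution(np.arange(0.05, 1.0, 0.1))
    assert np.allclose(dens, 0.1)


def test_positional_distribution_empty_and_bounds():
    assert positional_distribution([]) is None
    with pytest.raises(ValueError):
        positional_distribution([1.5])


def test_positional_distribution_three_prime_biased_sample():
    rng = np.random.default_rng(21)
    dens, mean = positional_distribution(rng.beta(3, 1, size=1000))
    assert mean > 0.6
    assert dens[-3:].sum() > dens[:3].sum()


def test_boxplot_summary_whiskers_within_range():
    rng = np.random.default_rng(2)
    g = _groups(a={"f": rng.normal(size=200)})
    row = boxplot_summary(g, ["f"]).iloc[0]
    assert row["q1"] <= row["median"] <= row["q3"]
    assert row["whisker_low"] >= row["q1"] - 1.5 * (row["q3"] - row["q1"]) - 1e-12
    assert row["whisker_high"] <= row["q3"] + 1.5 * (row["q3"] - row["q1"]) + 1e-12
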