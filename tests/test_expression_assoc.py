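"""Gene classes, expression-by-group comparisons, architecture enrichment."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest

from cisplice.expression_assoc import (
    architecture_enrichment,
    class_summary,
    classify_genes,
    expression_by_group,
)


def _ge(rows):
    return pd.DataFrame(rows, columns=["gene_id", "log2_fc", "p_value", "baseline_expr"])


def _as(rows):
    df = pd.DataFrame(rows, columns=["gene_id", "fold_change", "p_value"])
    for col, val in (("event_id", "e"), ("pattern", "EC"), ("chrom", "c"),
                     ("start", 0), ("end", 1), ("strand", "+"), ("direction", "up")):
        df[col] = val
    return df


def test_gene_with_only_splicing_event_is_as_only():
    ge = _ge([("g1", 0.1, 0.9, 2.0)])
    ev = _as([("g1", 4.0, 0.001)])
    table = classify_genes(ge, ev)
    assert table.set_index("gene_id").loc["g1", "class"] == "AS-only"


def test_gene_with_both_changes_is_ge_and_as():
    ge = _ge([("g1", 2.0, 0.001, 2.0)])
    ev = _as([("g1", 4.0, 0.001)])
    table = classify_genes(ge, ev).set_index("gene_id")
    assert table.loc["g1", "class"] == "GE&AS"
    assert table.loc["g1", "ge_direction"] == "up"


def test_twelve_gene_fixture_hand_tally():
    ge = _ge(
        [
            ("g01", 2.0, 0.01, 3.0),   # GE up
            ("g02", -1.5, 0.01, 3.0),  # GE down
            ("g03", 1.2, 0.01, 3.0),   # GE up + AS  -> GE&AS
            ("g04", 0.1, 0.9, 3.0),    # AS only
            ("g05", 0.0, 0.5, 3.0),    # unaffected
            ("g06", 3.0, 0.3, 3.0),    # p too high -> unaffected
            ("g07", 0.5, 0.001, 3.0),  # |fc| too small -> unaffected
            ("g08", -2.0, 0.05, 3.0),  # GE down (boundary p)
            ("g09", 1.0, 0.05, 3.0),   # GE up (boundary fc)
            ("g10", 0.0, 1.0, 3.0),    # AS only
            ("g11", 0.0, 1.0, -1.0),   # below expression floor -> excluded
            ("g12", 0.0, 1.0, 3.0),    # unaffected
        ]
    )
    ev = _as([("g03", 4.0, 0.001), ("g04", 2.0, 0.05), ("g10", 8.0, 1e-6),
              ("g04", 3.0, 0.2)])  # second g04 event not significant
    table = classify_genes(ge, ev)
    counts = table["class"].value_counts().to_dict()
    assert counts == {"unaffected": 4, "GE-only": 4, "AS-only": 2, "GE&AS": 1}
    assert len(table) == 11  # g11 excluded by the floor
    summary = class_summary(table).set_index("class")
    assert summary.loc["GE-only", "fraction_up"] == pytest.approx(2 / 4)


def test_classification_is_a_partition(small_bundle):
    table = classify_genes(small_bundle.expression, small_bundle.events)
    universe = (small_bundle.expression["baseline_expr"] >= 0).sum()
    orphans = len(table) - universe
    assert orphans >= 0
    assert table["class"].isin(["GE-only", "AS-only", "GE&AS", "unaffected"]).all()
    assert table["gene_id"].is_unique


def test_as_gene_missing_from_universe_counted_as_only():
    ge = _ge([("g1", 0.0, 1.0, 3.0)])
    ev = _as([("orphan", 4.0, 0.001)])
    table = classify_genes(ge, ev).set_index("gene_id")
    assert table.loc["orphan", "class"] == "AS-only"


def test_expression_identical_sets_p_one():
    ge = _ge([(f"g{i}", 0.0, 1.0, float(i)) for i in range(10)])
    sets = {"unaffected": [f"g{i}" for i in range(10)], "x": [f"g{i}" for i in range(10)]}
    res = expression_by_group(ge, sets).set_index("set")
    assert res.loc["x", "p_value"] == pytest.approx(1.0)
    assert res.loc["x", "median_log2_fpkm"] == res.loc["unaffected", "median_log2_fpkm"]


def test_expression_shifted_set_detected():
    rng = np.random.default_rng(17)
    base = rng.normal(3.0, 1.5, 1000)
    shifted = rng.normal(4.0, 1.5, 300)
    ge = _ge(
        [(f"u{i}", 0.0, 1.0, v) for i, v in enumerate(base)]
        + [(f"s{i}", 0.0, 1.0, v) for i, v in enumerate(shifted)]
    )
    sets = {
        "unaffected": [f"u{i}" for i in range(1000)],
        "regulated": [f"s{i}" for i in range(300)],
    }
    res = expression_by_group(ge, sets).set_index("set")
    assert res.loc["regulated", "median_log2_fpkm"] > res.loc["unaffected", "median_log2_fpkm"]
    assert res.loc["regulated", "p_value"] < 0.01


def test_singleton_set_reports_without_test():
    ge = _ge([("g1", 0, 1, 1.0), ("g2", 0, 1, 2.0), ("g3", 0, 1, 3.0), ("g4", 0, 1, 9.0)])
    res = expression_by_group(
        ge, {"unaffected": ["g1", "g2", "g3"], "solo": ["g4"]}
    ).set_index("set")
    assert res.loc["solo", "n"] == 1
    assert math.isnan(res.loc["solo", "p_value"])


def _arch(n_universe=200, n_intronless=10, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_universe):
        intronless = i < n_intronless
        rows.append(
            {
                "gene_id": f"g{i}",
                "gene_length": float(rng.integers(300, 1000)) if intronless
                else float(rng.integers(2000, 20000)),
                "mean_intron_length": 0.0 if intronless else float(rng.integers(100, 2000)),
                "intron_exon_ratio": 0.0 if intronless else rng.random() * 3,
                "intronless": intronless,
                "n_introns": 0 if intronless else int(rng.integers(1, 9)),
            }
        )
    return pd.DataFrame(rows)


def test_intronless_set_has_fraction_one():
    arch = _arch()
    sets = {"unaffected": [f"g{i}" for i in range(10, 200)],
            "up": [f"g{i}" for i in range(10)]}
    res = architecture_enrichment(sets, arch)
    row = res[(res["set"] == "up") & (res["feature"] == "intronless_fraction")].iloc[0]
    assert row["value_set"] == 1.0


def test_intronless_enrichment_detected():
    rng = np.random.default_rng(31)
    arch = _arch(n_universe=600, n_intronless=60, seed=31)
    # "GE-up" set: 50% intronless vs ~5% background among the unaffected rest
    up = [f"g{i}" for i in range(30)] + [f"g{i}" for i in range(100, 130)]
    rest = [f"g{i}" for i in range(130, 600)] + [f"g{i}" for i in range(30, 60)]
    res = architecture_enrichment({"unaffected": rest, "GE-up": up}, arch)
    fisher = res[(res["set"] == "GE-up") & (res["feature"] == "intronless_fraction")].iloc[0]
    assert fisher["p_value"] < 0.01
    length = res[(res["set"] == "GE-up") & (res["feature"] == "gene_length")].iloc[0]
    assert length["value_set"] < length["value_ref"] and length["p_value"] < 0.01


def test_set_equal_to_reference_gives_p_one():
    arch = _arch()
    all_genes = [f"g{i}" for i in range(200)]
    res = architecture_enrichment({"unaffected": all_genes, "same": all_genes}, arch)
    assert np.allclose(res["p_value"].dropna(), 1.0)
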