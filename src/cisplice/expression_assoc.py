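"""Gene-level analyses: expression/splicing overlap classes, expression of
regulated versus unaffected genes, and gene-architecture associations.

The expression universe is the set of genes whose baseline expression
(log2 FPKM) is at or above a configurable floor (default 0).  "Unaffected"
genes are expressed genes with neither a significant expression change nor
a significant splicing event — the reference set for all comparisons here.
All test statistics reduce to the group_stats primitives.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from cisplice.annotation_io import filter_significant
from cisplice.group_stats import benjamini_hochberg, fisher_enrichment, welch_t

logger = logging.getLogger(__name__)

GENE_CLASSES = ("GE-only", "AS-only", "GE&AS", "unaffected")


def classify_genes(
    ge_table: pd.DataFrame,
    as_events: pd.DataFrame,
    fc_threshold: float = 2.0,
    p_threshold: float = 0.05,
    expression_floor: float = 0.0,
) -> pd.DataFrame:
    """Partition expressed genes into GE-only / AS-only / GE&AS / unaffected.

    ``ge_table`` is the full differential-expression table (the universe);
    ``as_events`` the differential splicing-event table.  Significance uses
    the inclusive fold-change/p-value filter on both.  A gene hosting a
    significant event but absent from the expression universe is counted
    AS-only with a warning.  Returns one row per gene: class and
    ge_direction (up/down/none).
    """
    universe = ge_table.loc[ge_table["baseline_expr"] >= expression_floor]
    sig_ge = filter_significant(universe, fc_threshold, p_threshold)
    sig_as = filter_significant(as_events, fc_threshold, p_threshold)

    ge_dir = {
        r.gene_id: ("up" if r.log2_fc > 0 else "down")
        for r in sig_ge.itertuples(index=False)
    }
    as_genes = set(sig_as["gene_id"])
    universe_genes = list(universe["gene_id"])

    orphans = as_genes - set(universe_genes)
    if orphans:
        logger.warning(
            "%d AS-regulated gene(s) absent from the expression universe; "
            "counted as AS-only", len(orphans)
        )

    rows = []
    for gid in universe_genes + sorted(orphans):
        has_ge = gid in ge_dir
        has_as = gid in as_genes
        cls = (
            "GE&AS" if has_ge and has_as
            else "GE-only" if has_ge
            else "AS-only" if has_as
            else "unaffected"
        )
        rows.append({"gene_id": gid, "class": cls,
                     "ge_direction": ge_dir.get(gid, "none")})
    return pd.DataFrame(rows)


def class_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Class counts with per-class up/down fractions of GE-regulated genes."""
    rows = []
    for cls, sub in table.groupby("class", sort=True):
        n = len(sub)
        n_up = int((sub["ge_direction"] == "up").sum())
        n_down = int((sub["ge_direction"] == "down").sum())
        reg = n_up + n_down
        rows.append({
            "class": cls, "count": n,
            "fraction_up": n_up / reg if reg else np.nan,
            "fraction_down": n_down / reg if reg else np.nan,
        })
    return pd.DataFrame(rows)


def expression_by_group(
    ge_table: pd.DataFrame,
    gene_sets: Mapping[str, Sequence[str]],
    reference: str = "unaffected",
) -> pd.DataFrame:
    """Per-set size and median baseline expression, with a Welch comparison
    against the reference set.

    ``gene_sets`` maps set label -> gene ids; it must contain the reference
    label.  Missing expression values are dropped; an empty set yields a
    row with missing statistics; a singleton set reports its median but no
    test.
    """
    expr = ge_table.set_index("gene_id")["baseline_expr"]
    ref_vals = expr.reindex(gene_sets[reference]).dropna().to_numpy()
    rows = []
    for label, genes in gene_sets.items():
        vals = expr.reindex(list(genes)).dropna().to_numpy()
        row = {
            "set": label,
            "n": int(vals.size),
            "median_log2_fpkm": float(np.median(vals)) if vals.size else np.nan,
            "mean_log2_fpkm": float(vals.mean()) if vals.size else np.nan,
            "t_stat": np.nan, "df": np.nan, "p_value": np.nan,
        }
        if label != reference and vals.size >= 2 and ref_vals.size >= 2:
            try:
                t, df, p = welch_t(vals, ref_vals)
                row.update(t_stat=t, df=df, p_value=p)
            except ValueError:
                pass
        rows.append(row)
    out = pd.DataFrame(rows)
    out["p_adj"] = benjamini_hochberg(out["p_value"])
    return out


CONTINUOUS_ARCH_FEATURES = ("gene_length", "mean_intron_length", "intron_exon_ratio")


def architecture_enrichment(
    gene_sets: Mapping[str, Sequence[str]],
    architectures: pd.DataFrame,
    reference: str = "unaffected",
) -> pd.DataFrame:
    """Gene-architecture comparisons of each set against the reference.

    Welch tests on gene length, mean intron length and intron/exon ratio;
    Fisher exact on the intronless fraction; BH across all rows.
    ``architectures`` is the per-gene table for the whole universe
    (columns as produced by cis_features.architectures_frame).
    """
    arch = architectures.set_index("gene_id")
    ref = arch.reindex(gene_sets[reference]).dropna(how="all")
    rows = []
    for label, genes in gene_sets.items():
        if label == reference:
            continue
        sub = arch.reindex(list(genes)).dropna(how="all")
        for feat in CONTINUOUS_ARCH_FEATURES:
            a = sub[feat].dropna().to_numpy(dtype=float)
            b = ref[feat].dropna().to_numpy(dtype=float)
            row = {
                "set": label, "feature": feat, "test": "welch_t",
                "n_set": int(a.size), "n_ref": int(b.size),
                "value_set": float(a.mean()) if a.size else np.nan,
                "value_ref": float(b.mean()) if b.size else np.nan,
                "statistic": np.nan, "p_value": np.nan,
            }
            if a.size >= 2 and b.size >= 2:
                try:
                    t, _, p = welch_t(a, b)
                    row.update(statistic=t, p_value=p)
                except ValueError:
                    pass
            rows.append(row)
        k_set = int(sub["intronless"].sum())
        k_ref = int(ref["intronless"].sum())
        res = fisher_enrichment(k_set, len(sub), k_ref, len(ref), "intronless")
        rows.append({
            "set": label, "feature": "intronless_fraction", "test": "fisher_exact",
            "n_set": len(sub), "n_ref": len(ref),
            "value_set": k_set / len(sub) if len(sub) else np.nan,
            "value_ref": k_ref / len(ref) if len(ref) else np.nan,
            "statistic": res.odds_ratio if res else np.nan,
            "p_value": res.p_value if res else np.nan,
        })
    out = pd.DataFrame(rows)
    if len(out):
        out["p_adj"] = benjamini_hochberg(out["p_value"])
    return out
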