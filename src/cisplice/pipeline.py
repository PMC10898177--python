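"""End-to-end orchestration: from annotation + differential tables to the
full result bundle (event classification, pattern shares and enrichment,
cis-feature comparisons, positional distributions, expression and
gene-architecture associations).

The same functions back both the command-line workflow (file-based) and
the validation harness (in-memory synthetic bundles).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from cisplice import annotation_io, cis_features, event_catalog, expression_assoc, group_stats
from cisplice.annotation_io import EventRecord, GeneModel, SequenceAccessor
from cisplice.cis_features import Pwm
from cisplice.event_catalog import Catalog, CatalogEvent

FEATURE_LIST = [
    "ss5_score",
    "ss3_score",
    "bp_distance",
    "bp_score",
    "ppt_length",
    "ppt_score",
    "gc_event",
    "gc_up_flank",
    "gc_down_flank",
    "len_event",
    "len_up_flank",
    "len_down_flank",
    "rel_position",
]

# group pair -> the published contrast it mirrors: regulated events against
# reference alternative events of the same kind and against constitutive
# exons/introns
DEFAULT_PAIRS = [
    ("up_EC", "ref_cassette"),
    ("down_EC", "ref_cassette"),
    ("up_EC", "ref_constitutive_exon"),
    ("down_EC", "ref_constitutive_exon"),
    ("up_IR", "ref_IR"),
    ("up_IR", "ref_constitutive_intron"),
    ("down_IR", "ref_constitutive_intron"),
]


@dataclass
class AnalysisResult:
    classified_events: list[EventRecord]
    pattern_shares: pd.DataFrame
    enrichment: pd.DataFrame
    features_by_group: dict[str, pd.DataFrame]
    comparisons: pd.DataFrame
    positional: pd.DataFrame
    gene_classes: pd.DataFrame
    class_summary: pd.DataFrame
    expression_groups: pd.DataFrame
    architecture: pd.DataFrame
    architecture_tests: pd.DataFrame
    warnings: list[str] = field(default_factory=list)

    def tables(self) -> dict[str, pd.DataFrame]:
        out = {
            "pattern_shares": self.pattern_shares,
            "enrichment": self.enrichment,
            "comparisons": self.comparisons,
            "positional": self.positional,
            "gene_classes": self.gene_classes,
            "class_summary": self.class_summary,
            "expression_groups": self.expression_groups,
            "architecture": self.architecture,
            "architecture_tests": self.architecture_tests,
        }
        for label, df in self.features_by_group.items():
            out[f"features_{label}"] = df
        return out


def _pseudo_events(regions, gene_id, pattern) -> list[CatalogEvent]:
    return [CatalogEvent(pattern, gene_id, "", "", s, e) for s, e in regions]


def build_comparison_groups(
    events: Sequence[EventRecord],
    catalog: Catalog,
    genes_by_id: Mapping[str, GeneModel],
    rng: np.random.Generator,
    n_reference: int = 500,
) -> dict[str, list]:
    """Assemble the comparison groups from classified events and the
    catalogue reference sets.

    Regulated groups are split by pattern and direction (up_EC, down_EC,
    up_IR, down_IR).  Reference groups: not-regulated catalogued cassette
    exons (ref_cassette), not-regulated annotated retained introns
    (ref_IR), constitutive internal exons (ref_constitutive_exon) and
    constitutive introns (ref_constitutive_intron), each down-sampled to
    ``n_reference`` with the supplied RNG for tractability.
    """
    regulated = {(e.gene_id, e.start, e.end) for e in events}
    groups: dict[str, list] = {"up_EC": [], "down_EC": [], "up_IR": [], "down_IR": []}
    for e in events:
        key = f"{e.direction}_{e.pattern}"
        if key in groups:
            groups[key].append(e)

    def _sample(items, n):
        if len(items) <= n:
            return list(items)
        idx = rng.choice(len(items), size=n, replace=False)
        return [items[i] for i in sorted(idx)]

    ref_cassette = [
        ev for ev in catalog.cassette_exons
        if (ev.gene_id, ev.start, ev.end) not in regulated
    ]
    ref_ir = [
        ev for ev in catalog.retained_introns
        if (ev.gene_id, ev.start, ev.end) not in regulated
    ]
    const_introns = [
        CatalogEvent("constitutive_intron", gid, genes_by_id[gid].chrom,
                     genes_by_id[gid].strand, s, e)
        for gid, regions in sorted(catalog.constitutive_introns.items())
        for s, e in sorted(regions)
        if (gid, s, e) not in regulated and gid in genes_by_id
    ]
    # constitutive internal exons (with intron context on both sides)
    const_exons = []
    for gid, regions in sorted(catalog.constitutive_exons.items()):
        gene = genes_by_id.get(gid)
        if gene is None or len(gene.transcripts) == 0:
            continue
        t = cis_features.representative_transcript(gene)
        internal = set(t.exons[1:-1])
        for s, e in sorted(regions):
            if (s, e) in internal and (gid, s, e) not in regulated:
                const_exons.append(
                    CatalogEvent("constitutive_exon", gid, gene.chrom, gene.strand, s, e)
                )
    groups["ref_cassette"] = _sample(ref_cassette, n_reference)
    groups["ref_IR"] = _sample(ref_ir, n_reference)
    groups["ref_constitutive_exon"] = _sample(const_exons, n_reference)
    groups["ref_constitutive_intron"] = _sample(const_introns, n_reference)
    return groups


def analyze(
    genes: Sequence[GeneModel],
    accessor: SequenceAccessor,
    events_df: pd.DataFrame,
    expression_df: pd.DataFrame,
    seed: int = 0,
    fc_threshold: float = 2.0,
    p_threshold: float = 0.05,
    expression_floor: float = 0.0,
    n_reference: int = 500,
    n_bins: int = 10,
    donor_pwm: Pwm | None = None,
    acceptor_pwm: Pwm | None = None,
    branch_pwm: Pwm | None = None,
    group_pairs: Sequence[tuple[str, str]] = tuple(DEFAULT_PAIRS),
) -> AnalysisResult:
    """Run the full analysis.

    Splice-site PWMs are trained from the annotation's constitutive
    junctions unless supplied.  ``seed`` controls only the down-sampling of
    reference sets; everything else is deterministic.
    """
    rng = np.random.default_rng(seed)
    genes = list(genes)
    genes_by_id = {g.gene_id: g for g in genes}
    catalog = event_catalog.build_catalog(genes)

    sig = annotation_io.filter_significant(events_df, fc_threshold, p_threshold)
    records = annotation_io.events_from_frame(sig)
    classified = event_catalog.classify_events(records, catalog)
    shares = event_catalog.pattern_shares(classified)

    annotated = [e for e in classified if e.annotated]
    reg_counts = pd.Series([e.pattern for e in annotated]).value_counts().to_dict()
    cat_counts = pd.Series([e.pattern for e in catalog.events]).value_counts().to_dict()
    enrichment = group_stats.pattern_enrichment(reg_counts, cat_counts)

    if branch_pwm is None:
        branch_pwm = cis_features.shipped_branch_pwm()
    if donor_pwm is None or acceptor_pwm is None:
        donor_pwm, acceptor_pwm = cis_features.train_pwms(genes, accessor, catalog)

    groups = build_comparison_groups(classified, catalog, genes_by_id, rng, n_reference)
    features_by_group = {
        label: cis_features.features_frame(
            evs, genes_by_id, accessor, donor_pwm, acceptor_pwm, branch_pwm
        )
        for label, evs in groups.items()
    }
    pairs = [
        (a, b)
        for a, b in group_pairs
        if len(features_by_group.get(a, ())) >= 2 and len(features_by_group.get(b, ())) >= 2
    ]
    comparisons = group_stats.compare_groups(features_by_group, pairs, FEATURE_LIST)

    pos_rows = []
    for label in ("up_IR", "down_IR", "ref_constitutive_intron"):
        df = features_by_group.get(label)
        if df is None or not len(df):
            continue
        res = group_stats.positional_distribution(df["rel_position"], n_bins)
        if res is None:
            continue
        dens, mean = res
        row = {"group": label, "mean_rel_position": mean}
        row.update({f"bin_{i}": d for i, d in enumerate(dens)})
        pos_rows.append(row)
    positional = pd.DataFrame(pos_rows)

    gene_classes = expression_assoc.classify_genes(
        expression_df, events_df, fc_threshold, p_threshold, expression_floor
    )
    summary = expression_assoc.class_summary(gene_classes)
    by_class = {
        cls: gene_classes.loc[gene_classes["class"] == cls, "gene_id"].tolist()
        for cls in expression_assoc.GENE_CLASSES
    }
    ir_hosts = sorted({e.gene_id for e in classified if e.pattern == "IR"})
    gene_sets = {
        "unaffected": by_class["unaffected"],
        "AS-only": by_class["AS-only"],
        "GE-only": by_class["GE-only"],
        "GE&AS": by_class["GE&AS"],
        "IR-regulated": ir_hosts,
    }
    expression_groups = expression_assoc.expression_by_group(expression_df, gene_sets)
    architecture = cis_features.architectures_frame(genes)
    ge_dir = gene_classes.set_index("gene_id")["ge_direction"]
    arch_sets = {
        "unaffected": by_class["unaffected"],
        "GE-up": ge_dir.index[ge_dir == "up"].tolist(),
        "GE-down": ge_dir.index[ge_dir == "down"].tolist(),
        "AS-only": by_class["AS-only"],
    }
    architecture_tests = expression_assoc.architecture_enrichment(arch_sets, architecture)

    return AnalysisResult(
        classified_events=classified,
        pattern_shares=shares,
        enrichment=enrichment,
        features_by_group=features_by_group,
        comparisons=comparisons,
        positional=positional,
        gene_classes=gene_classes,
        class_summary=summary,
        expression_groups=expression_groups,
        architecture=architecture,
        architecture_tests=architecture_tests,
    )


def analyze_bundle(bundle, seed: int = 0, **kwargs) -> AnalysisResult:
    """Run the full analysis on an in-memory synthetic bundle."""
    return analyze(
        bundle.genes,
        bundle.accessor(),
        bundle.events,
        bundle.expression,
        seed=seed,
        **kwargs,
    )


# The headline parameter-recovery contrasts: (feature, group_a, group_b,
# expected sign of mean_a - mean_b under the default injected effects).
RECOVERY_CONTRASTS = [
    ("ss3_score", "up_EC", "ref_cassette", -1),
    ("ss3_score", "down_EC", "ref_cassette", +1),
    ("bp_distance", "down_EC", "ref_cassette", -1),
    ("gc_event", "down_EC", "ref_cassette", -1),
    ("len_event", "up_IR", "ref_constitutive_intron", -1),
    ("rel_position", "up_IR", "ref_constitutive_intron", +1),
]


def recovery_table(result: AnalysisResult) -> pd.DataFrame:
    """Extract the recovery contrasts from an analysis result: observed mean
    difference, raw Welch p, and whether the sign matches the injection."""
    comp = result.comparisons.set_index(["feature", "group_a", "group_b"])
    rows = []
    for feature, ga, gb, sign in RECOVERY_CONTRASTS:
        try:
            r = comp.loc[(feature, ga, gb)]
        except KeyError:
            continue
        diff = r["mean_a"] - r["mean_b"]
        rows.append(
            {
                "feature": feature,
                "group_a": ga,
                "group_b": gb,
                "expected_sign": sign,
                "mean_diff": diff,
                "p_value": r["p_value"],
                "sign_correct": bool(np.sign(diff) == sign),
            }
        )
    return pd.DataFrame(rows)
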