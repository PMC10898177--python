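"""Comparison groups and the statistical layer.

Welch's unequal-variance t-test (Satterthwaite degrees of freedom, not
rounded) for continuous features, two-sided Fisher exact tests for the
pattern-enrichment contrasts, Benjamini-Hochberg adjustment applied once
across a result set, and positional-distribution summaries.  Missing
feature values are dropped pairwise.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass
class ComparisonResult:
    feature: str
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    median_a: float
    median_b: float
    t_stat: float
    df: float
    p_value: float
    p_adj: float = math.nan


@dataclass
class EnrichmentResult:
    pattern: str
    k_regulated: int
    n_regulated: int
    k_catalog: int
    n_catalog: int
    odds_ratio: float
    p_value: float
    p_adj: float = math.nan


def welch_t(sample_a, sample_b) -> tuple[float, float, float]:
    """Welch's t statistic, Welch-Satterthwaite df and two-sided p.

    Requires >= 2 finite values per sample.  When both variances are zero:
    equal means give (0, nan->df, 1); unequal means are a degenerate
    comparison and raise.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs >= 2 finite values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    ma, mb = a.mean(), b.mean()
    if va == 0.0 and vb == 0.0:
        if ma == mb:
            return 0.0, float(a.size + b.size - 2), 1.0
        raise ValueError("degenerate zero-variance comparison")
    sa, sb = va / a.size, vb / b.size
    t = (ma - mb) / math.sqrt(sa + sb)
    df = (sa + sb) ** 2 / (
        sa**2 / (a.size - 1) + sb**2 / (b.size - 1)
    )
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(min(p, 1.0))


def fisher_enrichment(
    k_reg: int, n_reg: int, k_cat: int, n_cat: int, pattern: str = ""
) -> EnrichmentResult | None:
    """Two-sided Fisher exact test on [[k_reg, n_reg-k_reg], [k_cat, n_cat-k_cat]].

    Two-sided means the sum over hypergeometric outcomes with probability
    <= the observed table's.  Returns None when either universe is empty.
    """
    for k, n in ((k_reg, n_reg), (k_cat, n_cat)):
        if k < 0 or n < 0 or k > n:
            raise ValueError("counts must be non-negative with k <= n")
    if n_reg == 0 or n_cat == 0:
        return None
    table = [[k_reg, n_reg - k_reg], [k_cat, n_cat - k_cat]]
    odds_ratio, p = stats.fisher_exact(table, alternative="two-sided")
    return EnrichmentResult(pattern, k_reg, n_reg, k_cat, n_cat, float(odds_ratio), float(p))


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """BH step-up adjusted p-values; NaNs pass through unadjusted."""
    p = np.asarray(p_values, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def compare_groups(
    features_by_group: Mapping[str, pd.DataFrame],
    group_pairs: Sequence[tuple[str, str]],
    feature_list: Sequence[str],
) -> pd.DataFrame:
    """Welch comparisons for every (feature, group pair), BH-adjusted once
    across the whole result set.

    ``features_by_group`` maps a group label (e.g. ``up_EC``,
    ``ref_cassette``, ``ref_constitutive``) to its feature matrix.  Missing
    values are dropped pairwise; a group with fewer than 2 usable values
    still yields a row, with the test fields missing.
    """
    rows: list[ComparisonResult] = []
    for ga, gb in group_pairs:
        fa, fb = features_by_group[ga], features_by_group[gb]
        for feat in feature_list:
            a = fa[feat].to_numpy(dtype=float) if feat in fa else np.array([])
            b = fb[feat].to_numpy(dtype=float) if feat in fb else np.array([])
            a, b = a[np.isfinite(a)], b[np.isfinite(b)]
            base = dict(
                feature=feat,
                group_a=ga,
                group_b=gb,
                n_a=int(a.size),
                n_b=int(b.size),
                mean_a=float(a.mean()) if a.size else math.nan,
                mean_b=float(b.mean()) if b.size else math.nan,
                median_a=float(np.median(a)) if a.size else math.nan,
                median_b=float(np.median(b)) if b.size else math.nan,
            )
            try:
                t, df, p = welch_t(a, b)
            except ValueError:
                t = df = p = math.nan
            rows.append(ComparisonResult(**base, t_stat=t, df=df, p_value=p))
    out = pd.DataFrame([asdict(r) for r in rows])
    if len(out):
        out["p_adj"] = benjamini_hochberg(out["p_value"])
    return out


def pattern_enrichment(
    regulated_counts: Mapping[str, int],
    catalog_counts: Mapping[str, int],
) -> pd.DataFrame:
    """Per-pattern Fisher enrichment of regulated events against the
    annotated catalogue, BH across patterns.

    The published analysis calls this a "modified Fisher's test" without
    defining the modification; here it is the standard two-sided Fisher
    exact test (flagged in the ``test`` column).
    """
    n_reg = sum(regulated_counts.values())
    n_cat = sum(catalog_counts.values())
    rows = []
    for pattern in sorted(set(regulated_counts) | set(catalog_counts)):
        res = fisher_enrichment(
            regulated_counts.get(pattern, 0), n_reg,
            catalog_counts.get(pattern, 0), n_cat,
            pattern,
        )
        if res is not None:
            rows.append(asdict(res))
    out = pd.DataFrame(rows)
    if len(out):
        out["p_adj"] = benjamini_hochberg(out["p_value"])
        out["test"] = "fisher_exact_two_sided"
    return out


def positional_distribution(
    rel_positions: Sequence[float], n_bins: int = 10
) -> tuple[np.ndarray, float] | None:
    """Density over equal bins of [0, 1] (last bin closed at 1) and the mean.

    Densities sum to 1.  Empty input -> None.
    """
    x = np.asarray(rel_positions, dtype=float)
    x = x[np.isfinite(x)]
    if x.size == 0:
        return None
    if np.any((x < 0) | (x > 1)):
        raise ValueError("relative positions must lie in [0, 1]")
    counts, _ = np.histogram(x, bins=n_bins, range=(0.0, 1.0))
    return counts / x.size, float(x.mean())


def boxplot_summary(features_by_group: Mapping[str, pd.DataFrame],
                    feature_list: Sequence[str]) -> pd.DataFrame:
    """Quartiles, 1.5*IQR whiskers and the mean, one row per group x feature
    (the plotting convention used for the published boxplots)."""
    rows = []
    for group, df in features_by_group.items():
        for feat in feature_list:
            if feat not in df:
                continue
            x = df[feat].to_numpy(dtype=float)
            x = x[np.isfinite(x)]
            if x.size == 0:
                continue
            q1, med, q3 = np.percentile(x, [25, 50, 75])
            iqr = q3 - q1
            lo = x[x >= q1 - 1.5 * iqr].min()
            hi = x[x <= q3 + 1.5 * iqr].max()
            rows.append(
                dict(group=group, feature=feat, n=int(x.size), q1=q1, median=med,
                     q3=q3, whisker_low=lo, whisker_high=hi, mean=float(x.mean()))
            )
    return pd.DataFrame(rows)
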