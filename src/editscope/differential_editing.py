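"""Differential editing between two conditions.

Per-site changes are tested with a two-sided Fisher's exact test on the
2x2 table of edited/unedited read counts, adjusted by Benjamini-Hochberg.
A global editing shift is assessed with a Wilcoxon signed-rank test over
per-site rate differences (paired, the default for a knockdown-vs-control
comparison of the same cells) or a Mann-Whitney test over pooled rates
(unpaired). Gene-level variation flags a gene when any of its sites is
significant; the dysregulated-gene overlap applies |log2 FC| > log2(fc)
and FDR < threshold symmetrically to two differential-expression tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass(frozen=True)
class GlobalShift:
    statistic_name: str
    statistic: float
    p_value: float
    direction: str  # {"increase", "decrease", "none"}
    n_sites: int


def per_site_test(
    n_alt_a: int, n_ref_a: int, n_alt_b: int, n_ref_b: int
) -> float:
    """Two-sided Fisher's exact p for the table [[alt_A, ref_A], [alt_B, ref_B]].

    Degenerate tables (a margin zero in both conditions) return p = 1.
    """
    if (n_alt_a + n_alt_b == 0) or (n_ref_a + n_ref_b == 0):
        return 1.0
    _, p = stats.fisher_exact(
        [[n_alt_a, n_ref_a], [n_alt_b, n_ref_b]], alternative="two-sided"
    )
    return float(p)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([], dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def compare_sites(
    sites_a: pd.DataFrame,
    sites_b: pd.DataFrame,
    min_depth: int = 10,
) -> pd.DataFrame:
    """Join two per-site editing tables on (contig, pos) and test each site.

    Both inputs need columns contig, pos, n_ref, n_alt (gene_id carried
    through when present). Sites must have informative depth
    (n_ref + n_alt) >= min_depth in both conditions to be tested.
    Returns a table with counts, rates, delta = rate_B - rate_A, p and
    BH q values.
    """
    keep = ["contig", "pos", "n_ref", "n_alt"]
    extra = [c for c in ("gene_id", "strand") if c in sites_a.columns]
    merged = sites_a[keep + extra].merge(
        sites_b[keep], on=["contig", "pos"], suffixes=("_a", "_b")
    )
    informative_a = merged["n_ref_a"] + merged["n_alt_a"]
    informative_b = merged["n_ref_b"] + merged["n_alt_b"]
    merged = merged[(informative_a >= min_depth) & (informative_b >= min_depth)]
    merged = merged.reset_index(drop=True)
    merged["rate_a"] = merged["n_alt_a"] / (merged["n_ref_a"] + merged["n_alt_a"])
    merged["rate_b"] = merged["n_alt_b"] / (merged["n_ref_b"] + merged["n_alt_b"])
    merged["delta"] = merged["rate_b"] - merged["rate_a"]
    merged["p_value"] = [
        per_site_test(row.n_alt_a, row.n_ref_a, row.n_alt_b, row.n_ref_b)
        for row in merged.itertuples()
    ]
    merged["q_value"] = bh_adjust(merged["p_value"].to_numpy())
    return merged


def global_shift(
    rates_a: Sequence[float],
    rates_b: Sequence[float],
    paired: bool = True,
) -> GlobalShift:
    """Test for a global editing-rate shift between conditions.

    Paired (default): Wilcoxon signed-rank over per-site differences of
    sites shared by both conditions, in matching order. Unpaired:
    Mann-Whitney U over the pooled rate distributions. Direction is the
    sign of the median difference (paired) or of the difference in
    medians (unpaired).
    """
    a = np.asarray(rates_a, dtype=float)
    b = np.asarray(rates_b, dtype=float)
    if paired:
        if a.size != b.size:
            raise ValueError("paired test requires equal-length rate vectors")
        if a.size == 0:
            raise ValueError("no shared sites with informative depth")
        diffs = b - a
        median_diff = float(np.median(diffs))
        if np.all(diffs == 0):
            return GlobalShift("wilcoxon_signed_rank", 0.0, 1.0, "none", int(a.size))
        statistic, p = stats.wilcoxon(diffs, zero_method="wilcox")
        name = "wilcoxon_signed_rank"
    else:
        if a.size == 0 or b.size == 0:
            raise ValueError("both conditions need at least one site")
        median_diff = float(np.median(b) - np.median(a))
        statistic, p = stats.mannwhitneyu(b, a, alternative="two-sided")
        name = "mann_whitney_u"
    if median_diff > 0:
        direction = "increase"
    elif median_diff < 0:
        direction = "decrease"
    else:
        direction = "none"
    return GlobalShift(name, float(statistic), float(p), direction, int(a.size))


def global_shift_from_comparison(
    comparison: pd.DataFrame, paired: bool = True
) -> GlobalShift:
    return global_shift(
        comparison["rate_a"].to_numpy(),
        comparison["rate_b"].to_numpy(),
        paired=paired,
    )


def gene_variation(
    comparisons: pd.DataFrame, q_threshold: float = 0.05
) -> pd.DataFrame:
    """Flag genes where any site changes significantly (min-q aggregation).

    Returns a gene table (gene_id, min q, site count) sorted by min q,
    restricted to genes with min q <= q_threshold.
    """
    if "gene_id" not in comparisons.columns:
        raise ValueError("comparison table lacks gene_id")
    per_gene = (
        comparisons.groupby("gene_id")
        .agg(min_q=("q_value", "min"), n_sites=("q_value", "size"))
        .reset_index()
    )
    flagged = per_gene[per_gene["min_q"] <= q_threshold]
    return flagged.sort_values(["min_q", "gene_id"]).reset_index(drop=True)


def overlap_dysregulated(
    table_a: pd.DataFrame,
    table_b: pd.DataFrame,
    fc: float = 2.0,
    fdr: float = 0.05,
) -> Tuple[Set[str], int, int]:
    """Overlap of dysregulated genes between two DE tables.

    Each table needs columns gene_id, fold_change (linear, > 0) and fdr.
    Selection is |log2 fold_change| > log2(fc) and fdr < threshold, so
    down-regulation by more than 1/fc counts symmetrically. Returns the
    intersection, its size, and the size of the first selection.
    """
    selected = []
    for label, table in (("A", table_a), ("B", table_b)):
        dup = table["gene_id"][table["gene_id"].duplicated()].unique()
        if len(dup):
            raise ValueError(f"duplicate gene_ids in table {label}: {sorted(dup)}")
        if (table["fold_change"] <= 0).any():
            raise ValueError(f"table {label}: fold_change must be positive")
        hit = (np.abs(np.log2(table["fold_change"])) > np.log2(fc)) & (
            table["fdr"] < fdr
        )
        selected.append(set(table.loc[hit, "gene_id"]))
    shared = selected[0] & selected[1]
    return shared, len(shared), len(selected[0])
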