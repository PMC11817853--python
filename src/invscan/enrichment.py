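"""Fisher-exact GO-term enrichment of genes inside candidate regions.

For each candidate region, genes are assigned by the midpoint rule
(configurable), each GO term is tested with a two-sided Fisher exact test
of in-region vs background gene counts, p-values are Benjamini–Hochberg
adjusted across all tested terms per region, and a term is reported only
if its adjusted p is at most alpha and it annotates at least ``min_genes``
distinct in-region genes.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests

GO_PATTERN = re.compile(r"^GO:\d{7}$")


def validate_annotation(ann: pd.DataFrame, gene2go: pd.DataFrame) -> None:
    if not (ann["start"] < ann["end"]).all():
        raise ValueError("gene annotation contains start >= end")
    bad = [t for t in gene2go["term"].unique() if not GO_PATTERN.match(str(t))]
    if bad:
        raise ValueError(f"malformed GO term ids: {bad[:5]}")


def genes_in_regions(
    ann: pd.DataFrame, regions, rule: str = "midpoint"
) -> dict[str, set[str]]:
    """Per-region gene sets.

    ``rule`` is one of ``midpoint`` (gene midpoint inside the 1-based
    inclusive span; the default), ``any-overlap``, or ``full-containment``.
    Regions are given as objects with chrom/start/end; keys of the result
    are ``chrom:start-end``.
    """
    out: dict[str, set[str]] = {}
    mid = (ann["start"] + ann["end"]) // 2
    for region in regions:
        key = f"{region.chrom}:{region.start}-{region.end}"
        on_chrom = ann["chrom"] == region.chrom
        if rule == "midpoint":
            sel = on_chrom & (mid >= region.start) & (mid <= region.end)
        elif rule == "any-overlap":
            sel = on_chrom & (ann["end"] >= region.start) & (ann["start"] <= region.end)
        elif rule == "full-containment":
            sel = on_chrom & (ann["start"] >= region.start) & (ann["end"] <= region.end)
        else:
            raise ValueError(f"unknown rule {rule!r}")
        out[key] = set(ann.loc[sel, "gene"])
    return out


@dataclass
class EnrichmentResult:
    region: str
    term: str
    in_with: int
    in_without: int
    bg_with: int
    bg_without: int
    direction: str  # over | under
    p_raw: float
    p_adjusted: float


def fisher_enrichment(
    gene_sets: dict[str, set[str]],
    ann: pd.DataFrame,
    gene2go: pd.DataFrame,
    min_genes: int = 10,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Two-sided Fisher exact enrichment per term per region with BH FDR.

    The background for each region is every annotated gene not in that
    region.  Reported terms satisfy adjusted p <= alpha AND at least
    ``min_genes`` distinct in-region genes carrying the term; direction
    (over/under-represented) is annotated from the odds ratio of the
    observed table versus expectation.
    """
    if min_genes < 1:
        raise ValueError("min_genes must be >= 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    validate_annotation(ann, gene2go)
    all_genes = set(ann["gene"])
    term_genes = gene2go.groupby("term")["gene"].agg(set)

    rows = []
    for region, in_genes in gene_sets.items():
        in_genes = in_genes & all_genes
        bg_genes = all_genes - in_genes
        n_in, n_bg = len(in_genes), len(bg_genes)
        tested = []
        for term, carriers in term_genes.items():
            a = len(carriers & in_genes)
            c = len(carriers & bg_genes)
            if a + c == 0:
                continue
            table = [[a, n_in - a], [c, n_bg - c]]
            p = fisher_exact(table, alternative="two-sided")[1]
            expected = (a + c) * n_in / (n_in + n_bg) if (n_in + n_bg) else 0.0
            direction = "over" if a > expected else "under"
            tested.append((region, term, a, n_in - a, c, n_bg - c, direction, p))
        if not tested:
            continue
        p_raw = np.array([t[-1] for t in tested])
        p_adj = multipletests(p_raw, method="fdr_bh")[1]
        for t, padj in zip(tested, p_adj):
            rows.append(t + (padj,))

    result = pd.DataFrame(
        rows,
        columns=[
            "region",
            "term",
            "in_with",
            "in_without",
            "bg_with",
            "bg_without",
            "direction",
            "p_raw",
            "p_adjusted",
        ],
    )
    if result.empty:
        return result
    keep = (result["p_adjusted"] <= alpha) & (result["in_with"] >= min_genes)
    return result[keep].sort_values(["region", "p_adjusted"]).reset_index(drop=True)
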