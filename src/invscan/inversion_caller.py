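"""Candidate inversion regions and per-individual karyotype calls.

Evidence is combined in the order the discovery analysis uses it: extended
high-LD blocks delimit a candidate span; PCA of the span splits samples
into three clusters along PC1 (the two homokaryotypes and the
heterokaryotypes); the top PC1-loading SNPs become diagnostic markers; the
mean polarized diagnostic dosage calls each individual AHom / Het / RHom;
heterozygosity by karyotype class and an FST scan between homokaryotypes
confirm the inversion signature and refine boundaries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from invscan.popgen_core import PCAResult, fst_scan, individual_heterozygosity, pca
from invscan.variant_io import GenotypeMatrix

logger = logging.getLogger(__name__)

KARYOTYPE_CLASSES = ("AHom", "Het", "RHom")


@dataclass
class CandidateRegion:
    """Chromosome span (1-based inclusive bp) with supporting evidence."""

    chrom: str
    start: int
    end: int
    evidence: set = field(default_factory=set)
    n_sites: int = 0

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError("region must have start < end")

    @property
    def span_bp(self) -> int:
        return self.end - self.start + 1


@dataclass
class KaryotypeCall:
    """Per-sample karyotype assignment for one region."""

    region: CandidateRegion
    samples: list[str]
    genotype: np.ndarray  # strings in {AHom, Het, RHom, unassigned}
    mean_dosage: np.ndarray  # mean polarized diagnostic dosage (NaN if unassigned)
    n_diagnostics_observed: np.ndarray
    diagnostic_sites: np.ndarray  # matrix site indices

    def to_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample": self.samples,
                "region_id": f"{self.region.chrom}:{self.region.start}-{self.region.end}",
                "genotype": self.genotype,
                "mean_dosage": self.mean_dosage,
                "n_diagnostics": self.n_diagnostics_observed,
            }
        )

    def class_indices(self, cls: str) -> np.ndarray:
        return np.flatnonzero(self.genotype == cls)


def detect_ld_blocks(
    pairs: pd.DataFrame,
    r2_min: float = 0.8,
    min_span_bp: int = 1_000_000,
    max_gap_bp: int = 500_000,
) -> list[CandidateRegion]:
    """Merge high-LD pair intervals into candidate regions on one chromosome.

    Each pair with r² > ``r2_min`` is projected onto its bp interval
    [min(pos), max(pos)]; intervals separated by gaps <= ``max_gap_bp``
    are merged; merged spans of at least ``min_span_bp`` are returned,
    longest first.
    """
    if pairs.empty:
        return []
    chroms = set(pairs["CHR_A"]) | set(pairs["CHR_B"])
    if len(chroms) != 1:
        raise ValueError("detect_ld_blocks expects pairs from one chromosome")
    chrom = chroms.pop()
    hi = pairs[pairs["R2"] > r2_min]
    if hi.empty:
        return []
    lo_pos = np.minimum(hi["POS_A"].to_numpy(), hi["POS_B"].to_numpy())
    hi_pos = np.maximum(hi["POS_A"].to_numpy(), hi["POS_B"].to_numpy())
    order = np.argsort(lo_pos)
    merged: list[list[int]] = []
    for a, b in zip(lo_pos[order], hi_pos[order]):
        if merged and a <= merged[-1][1] + max_gap_bp:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([int(a), int(b)])
    regions = [
        CandidateRegion(chrom=chrom, start=a, end=b, evidence={"ld_block"})
        for a, b in merged
        if b - a + 1 >= min_span_bp
    ]
    regions.sort(key=lambda r: r.span_bp, reverse=True)
    return regions


def karyotype_by_pc1(
    m: GenotypeMatrix, region: CandidateRegion, min_sites: int = 20
) -> tuple[PCAResult, np.ndarray]:
    """PCA of a candidate region and a provisional 3-cluster split of PC1.

    1-D k-means (k=3) on PC1 scores, deterministically initialised at the
    minimum, median and maximum score; clusters are relabelled 0/1/2 along
    PC1 so the middle cluster is the provisional heterokaryotype class.
    A region where one karyotype class is absent yields a (flagged)
    near-empty cluster rather than an error.
    """
    idx = m.sites_in(region.chrom, region.start, region.end)
    sub = m.take_sites(idx)
    poly = np.nanstd(sub.dosage, axis=0) > 0
    if poly.sum() < min_sites:
        raise ValueError(
            f"region {region.chrom}:{region.start}-{region.end} has "
            f"{int(poly.sum())} polymorphic sites (< {min_sites})"
        )
    region.n_sites = len(idx)
    res = pca(sub, k=min(2, sub.n_samples - 1))
    pc1 = res.scores[:, 0]
    if len(np.unique(pc1)) < 3:
        raise ValueError("fewer than 3 distinct PC1 values")
    init = np.array([[pc1.min()], [np.median(pc1)], [pc1.max()]])
    km = KMeans(n_clusters=3, init=init, n_init=1, max_iter=300)
    labels = km.fit_predict(pc1[:, None])
    order = np.argsort(km.cluster_centers_.ravel())
    relabel = np.empty(3, dtype=int)
    relabel[order] = np.arange(3)
    labels = relabel[labels]
    sizes = np.bincount(labels, minlength=3)
    if (sizes == 0).any():
        logger.warning("degenerate PC1 cluster(s): sizes %s", sizes.tolist())
    return res, labels


def select_diagnostic_snps(
    pca_result: PCAResult,
    site_indices: np.ndarray,
    top_fraction: float = 0.05,
    min_count: int = 1,
) -> np.ndarray:
    """Sites with the highest |PC1 loading|.

    Ranks the region's sites by absolute PC1 loading (descending) and
    returns the top ``ceil(top_fraction * n_sites)`` (at least
    ``min_count``, capped at the region size) as matrix site indices;
    ties at the cutoff break by ascending position (matrix order).  The
    floor keeps the diagnostic panel usable on sparse regions, where 5%
    of a few dozen sites would leave fewer markers than the assignment
    rule needs.
    """
    if not 0 < top_fraction <= 1:
        raise ValueError("top_fraction must be in (0, 1]")
    load = np.abs(pca_result.loadings[:, 0])
    n_take = int(np.ceil(top_fraction * len(load)))
    n_take = min(max(n_take, min_count), len(load))
    # stable sort on (-|loading|, matrix order): ties keep earlier site
    order = np.lexsort((np.arange(len(load)), -load))
    return np.asarray(site_indices)[order[:n_take]]


def call_karyotypes(
    m: GenotypeMatrix,
    diagnostics: np.ndarray,
    anchor_group: np.ndarray,
    region: CandidateRegion,
    min_observed: int = 5,
) -> KaryotypeCall:
    """Assign AHom / Het / RHom from mean polarized diagnostic dosage.

    Each diagnostic site is polarized so the anchor group's (the samples
    assumed enriched for the ancestral arrangement) major allele counts as
    ancestral; the per-sample mean polarized dosage m over observed
    diagnostics is thresholded: AHom if m < 0.5, Het if 0.5 <= m <= 1.5,
    RHom if m > 1.5; samples observing fewer than ``min_observed``
    diagnostics are unassigned.
    """
    diagnostics = np.asarray(diagnostics)
    if diagnostics.size == 0:
        raise ValueError("no diagnostic sites")
    anchor_group = np.asarray(anchor_group)
    if anchor_group.size == 0:
        raise ValueError("empty anchor group")
    D = m.dosage[:, diagnostics]
    anchor = D[anchor_group]
    n_called = (~np.isnan(anchor)).sum(axis=0)
    if (n_called == 0).all():
        raise ValueError("anchor group entirely missing at all diagnostics")
    with np.errstate(invalid="ignore"):
        anchor_freq = np.nansum(anchor, axis=0) / (2.0 * np.maximum(n_called, 1))
    flip = anchor_freq > 0.5  # anchor major allele should be dosage 0
    P = np.where(flip[None, :], 2.0 - D, D)

    observed = (~np.isnan(P)).sum(axis=1)
    mean_dos = np.where(observed > 0, np.nansum(P, axis=1) / np.maximum(observed, 1), np.nan)
    genotype = np.full(m.n_samples, "unassigned", dtype=object)
    ok = observed >= min_observed
    genotype[ok & (mean_dos < 0.5)] = "AHom"
    genotype[ok & (mean_dos >= 0.5) & (mean_dos <= 1.5)] = "Het"
    genotype[ok & (mean_dos > 1.5)] = "RHom"
    mean_dos[~ok] = np.nan
    return KaryotypeCall(
        region=region,
        samples=list(m.samples),
        genotype=np.asarray(genotype),
        mean_dosage=mean_dos,
        n_diagnostics_observed=observed,
        diagnostic_sites=diagnostics,
    )


def default_anchor_group(
    m: GenotypeMatrix, diagnostics: np.ndarray, lineages: np.ndarray
) -> np.ndarray:
    """Anchor = samples of the lineage with the lowest mean diagnostic
    dosage under an arbitrary initial polarity (used when no anchor is
    supplied; ancestral-arrangement-enriched lineages score lowest once
    polarity is consistent)."""
    D = m.dosage[:, np.asarray(diagnostics)]
    best, best_val = None, np.inf
    for lin in pd.unique(lineages):
        idx = np.flatnonzero(lineages == lin)
        val = np.nanmean(D[idx])
        if val < best_val:
            best, best_val = lin, val
    return np.flatnonzero(lineages == best)


def heterozygosity_by_karyotype(
    m: GenotypeMatrix, call: KaryotypeCall
) -> pd.DataFrame:
    """Median and quartiles of individual heterozygosity over the region's
    sites, per karyotype class; classes without samples are omitted."""
    idx = m.sites_in(call.region.chrom, call.region.start, call.region.end)
    het = individual_heterozygosity(m, idx)
    rows = []
    for cls in KARYOTYPE_CLASSES:
        members = call.class_indices(cls)
        vals = het[members]
        vals = vals[~np.isnan(vals)]
        if len(vals) == 0:
            continue
        rows.append(
            (
                cls,
                len(vals),
                float(np.percentile(vals, 25)),
                float(np.median(vals)),
                float(np.percentile(vals, 75)),
            )
        )
    return pd.DataFrame(rows, columns=["genotype", "n", "q1", "median", "q3"])


def fst_confirm(
    m: GenotypeMatrix,
    call: KaryotypeCall,
    flank_bp: int = 2_000_000,
    roll_window: int = 25,
    run_threshold_mult: float = 5.0,
    run_threshold_floor: float = 0.05,
    elevated_mean: float = 0.25,
    snap_fraction: float = 0.5,
    sample_subset: np.ndarray | None = None,
) -> tuple[pd.DataFrame, CandidateRegion | None]:
    """FST scan between homokaryotype classes across the region and flanks.

    Scans Weir–Cockerham FST between AHom and RHom samples over the region
    plus ``flank_bp`` on each side.  The elevated segment is the longest
    run where a ``roll_window``-SNP centered rolling median exceeds
    ``run_threshold_mult`` times the flank median (floored at
    ``run_threshold_floor``, since a null flank median can be ~0 or
    negative); its endpoints are then snapped inward to the outermost
    sites whose own FST reaches ``snap_fraction`` of the run's median —
    the rolling median alone bleeds by up to half a window where flanking
    sites are sparse, while single strongly differentiated sites mark the
    edge of suppressed recombination sharply.  The region's
    ``fst_elevated`` evidence flag is set when the mean FST inside the
    original span is >= ``elevated_mean``.  Returns (scan table, refined
    region or None).
    """
    region = call.region
    a_idx = call.class_indices("AHom")
    r_idx = call.class_indices("RHom")
    if sample_subset is not None:
        sample_subset = np.asarray(sample_subset)
        a_idx = np.intersect1d(a_idx, sample_subset)
        r_idx = np.intersect1d(r_idx, sample_subset)
    if len(a_idx) < 2 or len(r_idx) < 2:
        logger.warning(
            "fst_confirm skipped: %d AHom / %d RHom homokaryotypes", len(a_idx), len(r_idx)
        )
        return pd.DataFrame(columns=["chrom", "pos", "fst"]), None

    lo = max(1, region.start - flank_bp)
    hi = region.end + flank_bp
    idx = m.sites_in(region.chrom, lo, hi)
    sub = m.take_sites(idx)
    scan = fst_scan(sub, a_idx, r_idx)
    pos = scan["pos"].to_numpy()
    fst = scan["fst"].to_numpy()

    inside = (pos >= region.start) & (pos <= region.end)
    flank = ~inside
    inside_vals = fst[inside & ~np.isnan(fst)]
    flank_vals = fst[flank & ~np.isnan(fst)]
    if len(inside_vals) and np.nanmean(inside_vals) >= elevated_mean:
        region.evidence.add("fst_elevated")

    flank_med = float(np.median(flank_vals)) if len(flank_vals) else 0.0
    threshold = max(run_threshold_mult * flank_med, run_threshold_floor)

    roll = (
        pd.Series(fst).rolling(roll_window, center=True, min_periods=1).median().to_numpy()
    )
    above = roll > threshold
    refined = None
    if above.any():
        # longest contiguous run above threshold
        best_len, best = 0, None
        start = None
        for i, flag in enumerate(np.append(above, False)):
            if flag and start is None:
                start = i
            elif not flag and start is not None:
                if i - start > best_len:
                    best_len, best = i - start, (start, i - 1)
                start = None
        s, e = best
        run_med = float(np.nanmedian(fst[s : e + 1]))
        snap = max(snap_fraction * run_med, threshold)
        strong = np.flatnonzero(~np.isnan(fst) & (fst >= snap))
        strong = strong[(strong >= s) & (strong <= e)]
        if strong.size:
            s, e = int(strong[0]), int(strong[-1])
        refined = CandidateRegion(
            chrom=region.chrom,
            start=int(pos[s]),
            end=int(pos[e]),
            evidence={"fst_elevated"} if "fst_elevated" in region.evidence else {"ld_block"},
        )
        refined.evidence.add("fst_run")
    return scan, refined


def frequency_by_location(call: KaryotypeCall, metadata: pd.DataFrame) -> pd.DataFrame:
    """Karyotype counts and inverted-arrangement frequency per sampling
    location: freq = (Het + 2*RHom) / (2 * assigned).  Locations with no
    assigned samples are omitted."""
    meta = metadata.set_index("sample")
    loc = np.array([meta.loc[s, "location"] for s in call.samples])
    rows = []
    for location in pd.unique(loc):
        sel = loc == location
        g = call.genotype[sel]
        n_a = int((g == "AHom").sum())
        n_h = int((g == "Het").sum())
        n_r = int((g == "RHom").sum())
        assigned = n_a + n_h + n_r
        if assigned == 0:
            continue
        rows.append(
            (location, n_a, n_h, n_r, (n_h + 2 * n_r) / (2.0 * assigned))
        )
    return pd.DataFrame(
        rows, columns=["location", "AHom", "Het", "RHom", "inverted_freq"]
    )
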