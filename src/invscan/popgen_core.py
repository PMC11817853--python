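"""Core population-genetic statistics: PCA, heterozygosity, pairwise r², FST.

These are the primitives every pipeline stage reuses.  PCA works on
mean-imputed, centered dosages (covariance PCA, no variance scaling by
default); r² is the squared Pearson correlation of genotype dosages over
pairwise-complete samples; FST is the Weir–Cockerham (1984) two-population
estimator in its allele-count (haploid ANOVA) formulation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from invscan.variant_io import GenotypeMatrix

logger = logging.getLogger(__name__)


@dataclass
class PCAResult:
    """scores: n_samples x k; loadings: n_sites x k (unit-norm columns);
    explained_variance_fraction: length-k, non-increasing."""

    scores: np.ndarray
    loadings: np.ndarray
    explained_variance_fraction: np.ndarray


def impute_center(dosage: np.ndarray, scale: bool = False) -> np.ndarray:
    """Mean-impute missing dosages per site and center each site.

    With ``scale=True`` each site is additionally divided by
    sqrt(p(1-p)) where p is the observed alternate-allele frequency.
    All-missing sites become all-zero columns.
    """
    X = dosage.copy()
    n_called = (~np.isnan(X)).sum(axis=0)
    with np.errstate(invalid="ignore"):
        mean = np.where(n_called > 0, np.nansum(X, axis=0) / np.maximum(n_called, 1), 0.0)
    idx = np.where(np.isnan(X))
    X[idx] = mean[idx[1]]
    X = X - mean
    if scale:
        p = mean / 2.0
        denom = np.sqrt(np.clip(p * (1.0 - p), 1e-12, None))
        X = X / denom
    return X


def pca(m: GenotypeMatrix, k: int, scale: bool = False) -> PCAResult:
    """Covariance PCA of the dosage matrix.

    Missing dosages are mean-imputed per site; sites are centered by mean
    dosage (no variance scaling unless ``scale``).  Sign convention: each
    loading column's largest-magnitude entry is positive.  Scores are the
    projections of the centered data on the loadings.
    """
    if m.n_samples < 2:
        raise ValueError("PCA needs at least 2 samples")
    if k > min(m.n_samples, m.n_sites):
        raise ValueError("k exceeds min(n_samples, n_sites)")
    X = impute_center(m.dosage, scale=scale)
    total_var = float((X**2).sum()) / (m.n_samples - 1)
    if total_var <= 0:
        raise ValueError("zero total variance (monomorphic input)")
    # SVD route: stable, gives loadings (V) and scores (U S) together
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    var = s**2 / (m.n_samples - 1)
    loadings = Vt[:k].T
    scores = U[:, :k] * s[:k]
    # fix signs so each loading column's largest-|.| entry is positive
    for j in range(loadings.shape[1]):
        i = np.argmax(np.abs(loadings[:, j]))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    return PCAResult(
        scores=scores,
        loadings=loadings,
        explained_variance_fraction=var[:k] / total_var,
    )


def individual_heterozygosity(m: GenotypeMatrix, site_subset=None) -> np.ndarray:
    """Per-sample fraction of heterozygous calls over a site subset.

    (# sites with dosage 1) / (# non-missing sites in the subset); NaN for
    samples with no called site in the subset.
    """
    if site_subset is None:
        D = m.dosage
    else:
        site_subset = np.asarray(site_subset)
        if site_subset.size == 0:
            raise ValueError("empty site subset")
        D = m.dosage[:, site_subset]
    called = (~np.isnan(D)).sum(axis=1)
    het = (D == 1).sum(axis=1)
    out = np.where(called > 0, het / np.maximum(called, 1), np.nan)
    n_empty = int((called == 0).sum())
    if n_empty:
        logger.warning("%d samples with zero called sites in subset", n_empty)
    return out


def _pairwise_r2_matrix(D: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs r² over pairwise-complete samples, vectorised.

    Returns (r2, n_shared) matrices; entries with <2 shared samples or a
    zero-variance member are NaN.
    """
    M = (~np.isnan(D)).astype(float)
    X = np.nan_to_num(D, nan=0.0)
    X2 = X * X
    n = M.T @ M
    sx = X.T @ M
    sy = M.T @ X
    sxx = X2.T @ M
    syy = M.T @ X2
    sxy = X.T @ X
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = sxy - sx * sy / n
        vx = sxx - sx * sx / n
        vy = syy - sy * sy / n
        r2 = (cov * cov) / (vx * vy)
    bad = (n < 2) | (vx <= 1e-12) | (vy <= 1e-12)
    r2[bad] = np.nan
    return r2, n


def pairwise_r2(
    m: GenotypeMatrix,
    site_indices=None,
    r2_report_min: float = 0.3,
    min_shared: int = 10,
) -> pd.DataFrame:
    """All-pairs genotypic r² with reporting thresholds.

    Pairs with r² below ``r2_report_min`` or fewer than ``min_shared``
    pairwise-complete samples are omitted.  Output columns mirror PLINK's
    ``.ld`` table: CHR_A, POS_A, CHR_B, POS_B, R2 (site A earlier in
    matrix order).
    """
    if site_indices is None:
        site_indices = np.arange(m.n_sites)
    site_indices = np.asarray(site_indices)
    if site_indices.size < 2:
        raise ValueError("need at least 2 sites")
    D = m.dosage[:, site_indices]
    r2, n = _pairwise_r2_matrix(D)
    iu, ju = np.triu_indices(site_indices.size, k=1)
    vals = r2[iu, ju]
    keep = (~np.isnan(vals)) & (vals >= r2_report_min) & (n[iu, ju] >= min_shared)
    ia = site_indices[iu[keep]]
    ib = site_indices[ju[keep]]
    s = m.sites
    return pd.DataFrame(
        {
            "CHR_A": s["chrom"].to_numpy()[ia],
            "POS_A": s["pos"].to_numpy()[ia],
            "CHR_B": s["chrom"].to_numpy()[ib],
            "POS_B": s["pos"].to_numpy()[ib],
            "R2": vals[keep],
            "IDX_A": ia,
            "IDX_B": ib,
        }
    )


def wc_fst_from_counts(n_a: float, alt_a: float, n_b: float, alt_b: float) -> float:
    """Weir–Cockerham FST from haploid allele counts of two populations.

    ``n_*`` are numbers of called alleles (2x diploids), ``alt_*`` the
    alternate-allele counts.  ANOVA form: theta = (MSP - MSG) /
    (MSP + (n_c - 1) MSG).  NaN when both populations are monomorphic for
    the same allele.
    """
    if n_a < 2 or n_b < 2:
        return np.nan
    p_a, p_b = alt_a / n_a, alt_b / n_b
    n_sum = n_a + n_b
    p_bar = (alt_a + alt_b) / n_sum
    if p_bar in (0.0, 1.0):
        return np.nan
    n_c = (n_sum - (n_a**2 + n_b**2) / n_sum)  # / (r - 1) with r = 2
    msp = n_a * (p_a - p_bar) ** 2 + n_b * (p_b - p_bar) ** 2  # / (r - 1)
    msg = (n_a * p_a * (1 - p_a) + n_b * p_b * (1 - p_b)) / (n_a - 1 + n_b - 1)
    denom = msp + (n_c - 1) * msg
    if denom == 0:
        return np.nan
    return (msp - msg) / denom


def fst_scan(m: GenotypeMatrix, group_a, group_b) -> pd.DataFrame:
    """Per-site Weir–Cockerham FST between two disjoint sample groups.

    Groups are arrays of sample indices.  Negative estimates are reported
    as-is; sites monomorphic across both groups (or with a group entirely
    missing) are NaN.  Returns (chrom, pos, fst).
    """
    group_a = np.asarray(group_a)
    group_b = np.asarray(group_b)
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("both groups need >= 2 samples")
    if np.intersect1d(group_a, group_b).size:
        raise ValueError("groups must be disjoint")
    fst = np.full(m.n_sites, np.nan)
    Da, Db = m.dosage[group_a], m.dosage[group_b]
    na = 2.0 * (~np.isnan(Da)).sum(axis=0)
    nb = 2.0 * (~np.isnan(Db)).sum(axis=0)
    alta = np.nansum(Da, axis=0)
    altb = np.nansum(Db, axis=0)
    for j in range(m.n_sites):
        fst[j] = wc_fst_from_counts(na[j], alta[j], nb[j], altb[j])
    return pd.DataFrame({"chrom": m.sites["chrom"], "pos": m.sites["pos"], "fst": fst})
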