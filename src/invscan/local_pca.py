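"""Windowed local PCA, window distances, classical MDS, and outlier windows.

Regions whose local population structure departs from the genome-wide
pattern (as chromosomal inversions do) are found by summarising each
non-overlapping window of SNPs with a low-rank PCA of its sample x sample
covariance, measuring pairwise distances between the normalised rank-k
covariance approximations, embedding the distance matrix with classical
(Torgerson) MDS, and flagging windows that are Tukey-rule outliers along
each MDS axis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from invscan.popgen_core import impute_center
from invscan.variant_io import GenotypeMatrix

logger = logging.getLogger(__name__)


@dataclass
class Window:
    """Consecutive block of sites on one chromosome (matrix indices,
    end-exclusive)."""

    index: int
    chrom: str
    site_start: int
    site_stop: int
    bp_start: int
    bp_end: int

    @property
    def site_indices(self) -> np.ndarray:
        return np.arange(self.site_start, self.site_stop)


@dataclass
class WindowPCA:
    """Rank-k spectral summary of one window's sample covariance."""

    window: Window
    eigenvalues: np.ndarray  # top-k, non-negative, non-increasing
    eigenvectors: np.ndarray  # n_samples x k, unit columns
    total_norm: float  # Frobenius norm of the full window covariance

    @property
    def k(self) -> int:
        return len(self.eigenvalues)

    def approx_covariance(self, normalized: bool = True) -> np.ndarray:
        """Explicit rank-k approximation sum_i lambda_i v_i v_i^T
        (divided by total_norm when ``normalized``)."""
        V = self.eigenvectors
        M = (V * self.eigenvalues) @ V.T
        return M / self.total_norm if normalized else M


@dataclass
class MDSResult:
    coords: np.ndarray  # n_windows x n_axes
    eigenvalues: np.ndarray
    window_indices: np.ndarray  # matrix of retained window ids, row-aligned


@dataclass
class OutlierSet:
    axis: int
    window_indices: np.ndarray
    fences: tuple[float, float]


def make_windows(m: GenotypeMatrix, window_snps: int) -> list[Window]:
    """Non-overlapping blocks of exactly ``window_snps`` sites per
    chromosome; the trailing remainder is discarded and windows never span
    chromosome boundaries."""
    if window_snps < 2:
        raise ValueError("window_snps must be >= 2")
    chroms = m.sites["chrom"].to_numpy()
    pos = m.sites["pos"].to_numpy()
    windows: list[Window] = []
    for chrom in pd.unique(chroms):
        idx = np.flatnonzero(chroms == chrom)
        n_win = len(idx) // window_snps
        if n_win == 0:
            logger.info("chromosome %s has < %d sites: no windows", chrom, window_snps)
        for w in range(n_win):
            block = idx[w * window_snps : (w + 1) * window_snps]
            windows.append(
                Window(
                    index=len(windows),
                    chrom=chrom,
                    site_start=int(block[0]),
                    site_stop=int(block[-1]) + 1,
                    bp_start=int(pos[block[0]]),
                    bp_end=int(pos[block[-1]]),
                )
            )
    return windows


def window_pca(m: GenotypeMatrix, window: Window, k: int = 2) -> WindowPCA:
    """Top-k eigenpairs of one window's n x n sample covariance.

    Missing dosages are mean-imputed within the window, sites centered,
    and the covariance taken across the window's sites.  Eigenvector sign:
    largest-magnitude entry positive.
    """
    X = impute_center(m.dosage[:, window.site_indices])
    if not np.any(X):
        raise ValueError(f"window {window.index}: all sites monomorphic")
    C = X @ X.T / max(X.shape[1] - 1, 1)
    vals, vecs = np.linalg.eigh(C)
    order = np.argsort(vals)[::-1][:k]
    vals = np.clip(vals[order], 0.0, None)
    vecs = vecs[:, order]
    for j in range(vecs.shape[1]):
        i = np.argmax(np.abs(vecs[:, j]))
        if vecs[i, j] < 0:
            vecs[:, j] *= -1
    return WindowPCA(
        window=window,
        eigenvalues=vals,
        eigenvectors=vecs,
        total_norm=float(np.linalg.norm(C, "fro")),
    )


def window_distance(a: WindowPCA, b: WindowPCA) -> float:
    """Frobenius distance between two normalised rank-k covariance
    approximations.

    Each window's approximation sum_i lambda_i v_i v_i^T is divided by the
    Frobenius norm of its full covariance before differencing, so the
    comparison is of structure rather than of per-window variance scale.
    Computed in the k x k eigenbasis; equals the explicit n x n matrix
    difference.
    """
    if a.k != b.k:
        raise ValueError("windows summarise different numbers of PCs")
    if a.eigenvectors.shape[0] != b.eigenvectors.shape[0]:
        raise ValueError("windows have different sample counts")
    la = a.eigenvalues / a.total_norm
    lb = b.eigenvalues / b.total_norm
    cross = a.eigenvectors.T @ b.eigenvectors  # k x k of v_i . w_j
    sq = float(np.sum(la**2) + np.sum(lb**2) - 2.0 * (la[:, None] * lb[None, :] * cross**2).sum())
    return float(np.sqrt(max(sq, 0.0)))


def distance_matrix(summaries: list[WindowPCA]) -> np.ndarray:
    """All-pairs window distances (symmetric, zero diagonal)."""
    n = len(summaries)
    k = summaries[0].k
    nsamp = summaries[0].eigenvectors.shape[0]
    L = np.stack([s.eigenvalues / s.total_norm for s in summaries])  # n x k
    V = np.stack([s.eigenvectors for s in summaries])  # n x nsamp x k
    # G[a, b, i, j] = (v_ai . v_bj)^2 contracted against lambda outer products
    flat = V.reshape(n, nsamp, k)
    sq_self = (L**2).sum(axis=1)
    D2 = sq_self[:, None] + sq_self[None, :]
    for a in range(n):
        cross = np.einsum("si,msj->mij", flat[a], flat)  # n x k x k
        D2[a] -= 2.0 * np.einsum("i,mj,mij->m", L[a], L, cross**2)
    D2 = np.clip(D2, 0.0, None)
    np.fill_diagonal(D2, 0.0)
    D = np.sqrt(D2)
    return (D + D.T) / 2.0


def classical_mds(distances: np.ndarray, n_axes: int = 3) -> MDSResult:
    """Classical (Torgerson) MDS of a distance matrix.

    Double-centers -D²/2, eigendecomposes, and scales eigenvectors by the
    square roots of the positive eigenvalues; axes are ordered by
    eigenvalue, with the sign fixed so each axis's largest-magnitude
    coordinate is positive.  A strongly negative eigenvalue (beyond half
    the largest) logs a non-Euclidean warning.
    """
    D = np.asarray(distances, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(D), 0.0, atol=1e-10):
        raise ValueError("distance matrix must have zero diagonal")
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    if n > 1 and vals[-1] < -0.5 * abs(vals[0]):
        logger.warning("strongly negative MDS eigenvalue: distances are non-Euclidean")
    n_axes = min(n_axes, n)
    coords = np.zeros((n, n_axes))
    for j in range(n_axes):
        if vals[j] > 0:
            coords[:, j] = vecs[:, j] * np.sqrt(vals[j])
        i = np.argmax(np.abs(coords[:, j]))
        if coords[i, j] < 0:
            coords[:, j] *= -1
    return MDSResult(coords=coords, eigenvalues=vals[:n_axes], window_indices=np.arange(n))


def tukey_hinges(x: np.ndarray) -> tuple[float, float]:
    """Lower and upper hinges as R's fivenum computes them (the quartile
    definition underlying boxplot.stats)."""
    x = np.sort(np.asarray(x, dtype=float))
    n = len(x)
    n4 = np.floor((n + 3) / 2) / 2
    d = np.array([n4, n + 1 - n4])
    lo = x[np.floor(d).astype(int) - 1]
    hi = x[np.ceil(d).astype(int) - 1]
    h = (lo + hi) / 2.0
    return float(h[0]), float(h[1])


def detect_outlier_windows(mds: MDSResult, axis: int, coef: float = 1.5) -> OutlierSet:
    """Tukey-rule outliers along one MDS axis (0-based).

    Quartiles are Tukey hinges, matching R's boxplot.stats; outliers lie
    outside [Q1 - coef*IQR, Q3 + coef*IQR].  Constant coordinates give an
    empty set.
    """
    x = mds.coords[:, axis]
    if len(x) < 5:
        raise ValueError("need at least 5 windows")
    q1, q3 = tukey_hinges(x)
    iqr = q3 - q1
    lo, hi = q1 - coef * iqr, q3 + coef * iqr
    out = (x < lo) | (x > hi)
    return OutlierSet(
        axis=axis,
        window_indices=mds.window_indices[out],
        fences=(lo, hi),
    )


def summarize_outliers(outliers: OutlierSet, windows: list[Window]) -> pd.DataFrame:
    """Per-chromosome outlier counts and percentage of this axis's outliers.

    Percentages are rounded to one decimal (so 9 of 25 prints 36.0).
    Empty when no outliers.
    """
    if len(outliers.window_indices) == 0:
        return pd.DataFrame(columns=["chrom", "n_outliers", "pct_of_axis"])
    chrom_of = {w.index: w.chrom for w in windows}
    chroms = pd.Series([chrom_of[i] for i in outliers.window_indices])
    counts = chroms.value_counts()
    total = int(counts.sum())
    out = pd.DataFrame(
        {
            "chrom": counts.index,
            "n_outliers": counts.to_numpy(),
            "pct_of_axis": np.round(100.0 * counts.to_numpy() / total, 1),
        }
    )
    return out.reset_index(drop=True)
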