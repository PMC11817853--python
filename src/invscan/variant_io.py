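"""Genotype matrix container, VCF round-trip, site filters, and LD pruning.

The central in-memory object is :class:`GenotypeMatrix`: individuals x
biallelic sites, stored as alternate-allele dosage {0, 1, 2} with ``NaN``
for missing genotypes.  Sites are kept sorted by (chromosome, position);
all downstream stages (PCA, LD, FST, windowing) operate on this container.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SITE_COLUMNS = ["chrom", "pos", "ref", "alt"]
METADATA_COLUMNS = ["sample", "location", "lineage", "data_type"]


@dataclass
class GenotypeMatrix:
    """Diploid dosage matrix over biallelic SNPs.

    Parameters
    ----------
    samples : list of str
        Ordered sample identifiers (rows of ``dosage``).
    sites : pandas.DataFrame
        One row per site with columns ``chrom, pos, ref, alt``; sorted by
        (chrom, pos), no duplicate positions within a chromosome.
    dosage : numpy.ndarray, float, shape (n_samples, n_sites)
        Alternate-allele dosage in {0, 1, 2}; missing is ``NaN``.
    """

    samples: list[str]
    sites: pd.DataFrame
    dosage: np.ndarray

    def __post_init__(self) -> None:
        self.sites = self.sites.reset_index(drop=True)
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.shape != (len(self.samples), len(self.sites)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.samples)} samples x {len(self.sites)} sites"
            )
        key = self.sites[["chrom", "pos"]]
        if key.duplicated().any():
            raise ValueError("duplicate (chrom, pos) in site table")
        ordered = self.sites.sort_values(["chrom", "pos"], kind="mergesort")
        if not np.array_equal(ordered.index.to_numpy(), np.arange(len(self.sites))):
            raise ValueError("sites must be sorted by (chrom, pos)")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def take_sites(self, index) -> "GenotypeMatrix":
        """Subset to the given site indices (kept in matrix order)."""
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        index = np.sort(index)
        return GenotypeMatrix(
            samples=list(self.samples),
            sites=self.sites.iloc[index],
            dosage=self.dosage[:, index],
        )

    def take_samples(self, index) -> "GenotypeMatrix":
        """Subset to the given sample indices (order preserved as given)."""
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeMatrix(
            samples=[self.samples[i] for i in index],
            sites=self.sites,
            dosage=self.dosage[index, :],
        )

    def sample_indices(self, names) -> np.ndarray:
        pos = {s: i for i, s in enumerate(self.samples)}
        return np.array([pos[n] for n in names], dtype=int)

    def sites_in(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Indices of sites on ``chrom`` with start <= pos <= end (1-based)."""
        s = self.sites
        mask = (s["chrom"] == chrom) & (s["pos"] >= start) & (s["pos"] <= end)
        return np.flatnonzero(mask.to_numpy())


def read_vcf(path) -> GenotypeMatrix:
    """Read a VCF with GT fields into a :class:`GenotypeMatrix`.

    Multi-allelic and non-SNP records are skipped (count logged); genotypes
    with any missing allele are treated as missing.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    if not samples:
        raise ValueError(f"{path}: VCF contains zero samples")
    rows = []
    dosages = []
    n_skipped = 0
    for rec in vcf:
        if len(rec.ALT) != 1 or not rec.is_snp:
            n_skipped += 1
            continue
        # gts012: 0/1/2 dosage, 3 = missing (includes half-missing calls)
        d = rec.gt_types.astype(float)
        d[d == 3] = np.nan
        rows.append((rec.CHROM, rec.POS, rec.REF, rec.ALT[0]))
        dosages.append(d)
    vcf.close()
    if n_skipped:
        logger.info("read_vcf: skipped %d multi-allelic/non-SNP records", n_skipped)
    sites = pd.DataFrame(rows, columns=SITE_COLUMNS)
    dosage = np.array(dosages, dtype=float).T if dosages else np.empty((len(samples), 0))
    order = sites.sort_values(["chrom", "pos"], kind="mergesort").index.to_numpy()
    return GenotypeMatrix(samples=samples, sites=sites.iloc[order], dosage=dosage[:, order])


def write_vcf(m: GenotypeMatrix, path) -> None:
    """Write a minimal VCF v4.2 (GT-only; ``./.`` for missing)."""
    gt_codes = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in m.sites["chrom"].unique():
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(m.samples) + "\n")
        for j, site in enumerate(m.sites.itertuples(index=False)):
            gts = "\t".join(
                "./." if np.isnan(d) else gt_codes[d] for d in m.dosage[:, j]
            )
            fh.write(f"{site.chrom}\t{site.pos}\t.\t{site.ref}\t{site.alt}\t.\tPASS\t.\tGT\t{gts}\n")


def read_metadata(path) -> pd.DataFrame:
    """Read the sample metadata TSV (sample, location, lineage, data_type)."""
    meta = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(METADATA_COLUMNS) - set(meta.columns)
    if missing:
        raise ValueError(f"metadata missing columns: {sorted(missing)}")
    return meta[METADATA_COLUMNS]


def write_metadata(meta: pd.DataFrame, path) -> None:
    meta[METADATA_COLUMNS].to_csv(path, sep="\t", index=False)


def filter_sites(m: GenotypeMatrix, min_presence: float, min_maf: float) -> GenotypeMatrix:
    """Retain sites called in >= ``min_presence`` of samples with MAF >= ``min_maf``.

    Both thresholds are inclusive.  MAF is computed from observed allele
    counts among non-missing genotypes.  Sample set and site order are
    unchanged; an empty result is a warning, not an error.
    """
    if not (0 < min_presence <= 1):
        raise ValueError("min_presence must be in (0, 1]")
    if not (0 <= min_maf < 0.5):
        raise ValueError("min_maf must be in [0, 0.5)")
    called = ~np.isnan(m.dosage)
    n_called = called.sum(axis=0)
    presence = n_called / m.n_samples
    with np.errstate(invalid="ignore"):
        alt_freq = np.nansum(m.dosage, axis=0) / (2.0 * np.maximum(n_called, 1))
    maf = np.minimum(alt_freq, 1.0 - alt_freq)
    keep = (presence >= min_presence) & (maf >= min_maf) & (n_called > 0)
    if not keep.any():
        logger.warning("filter_sites removed all %d sites", m.n_sites)
    else:
        logger.info("filter_sites: %d -> %d sites", m.n_sites, int(keep.sum()))
    return m.take_sites(keep)


def ld_prune(m: GenotypeMatrix, r2_max: float = 0.2, window_bp: int = 10_000) -> GenotypeMatrix:
    """Greedy left-to-right LD pruning per chromosome.

    Scanning sites in position order, a site is dropped when its squared
    Pearson dosage correlation with any already-retained site within
    ``window_bp`` upstream exceeds ``r2_max``.  Keep-first is deterministic
    and idempotent.
    """
    if not (0 < r2_max <= 1):
        raise ValueError("r2_max must be in (0, 1]")
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    keep = np.zeros(m.n_sites, dtype=bool)
    pos = m.sites["pos"].to_numpy()
    chroms = m.sites["chrom"].to_numpy()
    for chrom in pd.unique(chroms):
        idx = np.flatnonzero(chroms == chrom)
        retained: list[int] = []
        for j in idx:
            lo = pos[j] - window_bp
            # retained is position-ordered; only the tail can be in range
            check = [r for r in retained if pos[r] >= lo]
            drop = False
            for r in check:
                r2 = _pair_r2(m.dosage[:, r], m.dosage[:, j])
                if r2 is not None and r2 > r2_max:
                    drop = True
                    break
            if not drop:
                retained.append(j)
                keep[j] = True
    logger.info("ld_prune: %d -> %d sites", m.n_sites, int(keep.sum()))
    return m.take_sites(keep)


def _pair_r2(x: np.ndarray, y: np.ndarray) -> float | None:
    """Squared Pearson correlation over samples non-missing at both sites."""
    ok = ~(np.isnan(x) | np.isnan(y))
    if ok.sum() < 2:
        return None
    xs, ys = x[ok], y[ok]
    vx = xs.var()
    vy = ys.var()
    if vx == 0 or vy == 0:
        return None
    c = ((xs - xs.mean()) * (ys - ys.mean())).mean()
    return float(c * c / (vx * vy))
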