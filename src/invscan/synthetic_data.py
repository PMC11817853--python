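"""Synthetic genotype cohorts with known population structure and inversions.

The generator emulates the study design the downstream pipeline assumes:
three hierarchically diverged lineages (IND splitting first, SEA and
AUS+NG sharing an internal branch), one or more inversion loci with
suppressed recombination between arrangements, arrangement-specific fixed
differences, reduced diversity in the inverted arrangement, and a gradient
of inverted-arrangement frequencies across lineages (IND ~ 0, SEA
intermediate, AUS+NG ~ 1).  Background allele frequencies follow the
Balding-Nichols F-model; an ascertainment step emulates sparse shared RAD
loci versus dense WGS sites plus random missingness.

Every draw is taken from a single seeded generator, so the same config and
seed give bit-identical cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from invscan.variant_io import GenotypeMatrix, SITE_COLUMNS

# Frequencies from the F-model are clamped away from 0/1 so no background
# site is degenerate-monomorphic in every lineage.
_FREQ_FLOOR = 0.001

DEFAULT_LINEAGES = ("IND", "SEA", "AUSNG")


@dataclass
class InversionSpec:
    """One polymorphic inversion locus.

    Parameters
    ----------
    chromosome, span : location of the inverted segment (1-based inclusive bp).
    n_sites : number of SNPs simulated inside the span.
    fixed_diff_fraction : fraction of inversion sites fixed between
        arrangements (frequency 0 in the ancestral pool, 1 in the inverted).
    arrangement_divergence : F-like drift separating the two arrangement
        allele pools at non-fixed sites.
    inverted_pool_F : extra drift applied to the inverted pool only; pushes
        its frequencies toward 0/1 and so lowers inverted-homokaryotype
        heterozygosity.
    inverted_freq : per-lineage frequency q of the inverted arrangement.
    """

    chromosome: str
    span: tuple[int, int]
    n_sites: int
    fixed_diff_fraction: float = 0.3
    arrangement_divergence: float = 0.2
    inverted_pool_F: float = 0.3
    inverted_freq: dict[str, float] = field(
        default_factory=lambda: {"IND": 0.0, "SEA": 0.5, "AUSNG": 1.0}
    )

    def validate(self) -> None:
        start, end = self.span
        if not start < end:
            raise ValueError(f"inversion span must have start < end, got {self.span}")
        if not 0 <= self.fixed_diff_fraction <= 1:
            raise ValueError("fixed_diff_fraction must be in [0, 1]")
        for lineage, q in self.inverted_freq.items():
            if not 0 <= q <= 1:
                raise ValueError(f"inverted_freq[{lineage}]={q} outside [0, 1]")


@dataclass
class SimConfig:
    """Full generative configuration for one synthetic cohort.

    Defaults reproduce the standard study conditions used throughout the
    test-bench: 3 lineages x 50 samples, 5 chromosomes of 25 Mb, 5,000
    background SNPs, one 5 Mb inversion with 600 sites and an inverted-
    arrangement frequency gradient {IND: 0, SEA: 0.5, AUSNG: 1}, 30% RAD
    site retention and 10% random missingness.
    """

    n_per_lineage: dict[str, int] = field(
        default_factory=lambda: {"IND": 50, "SEA": 50, "AUSNG": 50}
    )
    chromosomes: list[tuple[str, int]] = field(
        default_factory=lambda: [(f"chr{i}", 25_000_000) for i in range(1, 6)]
    )
    n_background_snps: int = 5_000
    background_F: dict[str, float] = field(
        default_factory=lambda: {"IND": 0.15, "SEA": 0.05, "AUSNG": 0.08}
    )
    # drift of the internal (SEA, AUSNG) node off the root; gives the
    # (IND,(SEA,AUSNG)) topology its shared branch
    shared_branch_F: float = 0.08
    inversions: list[InversionSpec] = field(
        default_factory=lambda: [InversionSpec("chr3", (10_000_000, 15_000_000), 600)]
    )
    rad_site_fraction: float = 0.3
    missing_rate: float = 0.1
    # fraction of samples per lineage labelled RAD (the rest WGS)
    rad_sample_fraction: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if any(n < 0 for n in self.n_per_lineage.values()):
            raise ValueError("sample counts must be >= 0")
        if sum(self.n_per_lineage.values()) < 2:
            raise ValueError("need at least 2 samples in total")
        if not 0 < self.rad_site_fraction <= 1:
            raise ValueError("rad_site_fraction must be in (0, 1]")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        chrom_len = dict(self.chromosomes)
        seen = set()
        for inv in self.inversions:
            inv.validate()
            if inv.chromosome in seen:
                raise ValueError(f"more than one inversion on {inv.chromosome}")
            seen.add(inv.chromosome)
            if inv.chromosome not in chrom_len:
                raise ValueError(f"inversion chromosome {inv.chromosome} not in config")
            if inv.span[1] > chrom_len[inv.chromosome]:
                raise ValueError(
                    f"inversion span {inv.span} exceeds {inv.chromosome} length "
                    f"{chrom_len[inv.chromosome]}"
                )
            for lineage in self.n_per_lineage:
                if lineage not in inv.inverted_freq:
                    raise ValueError(f"inverted_freq missing lineage {lineage}")


@dataclass
class SimTruth:
    """Ground truth of a simulated cohort: per-individual karyotypes
    (count of inverted arrangements, 0/1/2) per inversion, true spans,
    realized pool frequencies, and the generating config."""

    config: SimConfig
    karyotypes: pd.DataFrame  # sample, lineage, chromosome, karyotype
    spans: dict[str, tuple[int, int]]  # chromosome -> true span
    fixed_diff_sites: dict[str, np.ndarray]  # chromosome -> positions
    pool_freqs: dict[str, pd.DataFrame]  # chromosome -> pos, anc_freq, inv_freq

    def karyotype_vector(self, chromosome: str) -> np.ndarray:
        k = self.karyotypes
        sub = k[k["chromosome"] == chromosome]
        return sub["karyotype"].to_numpy()

    def to_table(self) -> pd.DataFrame:
        return self.karyotypes.copy()


def _balding_nichols(rng: np.random.Generator, p: np.ndarray, F: float) -> np.ndarray:
    """Draw descendant allele frequencies around ancestral ``p`` with drift F.

    Beta(p(1-F)/F, (1-p)(1-F)/F); F -> 0 returns p unchanged.  Draws are
    clamped to [0.001, 0.999].
    """
    p = np.asarray(p, dtype=float)
    if F <= 0:
        return p.copy()
    scale = (1.0 - F) / F
    q = rng.beta(p * scale, (1.0 - p) * scale)
    return np.clip(q, _FREQ_FLOOR, 1.0 - _FREQ_FLOOR)


def _draw_positions(rng: np.random.Generator, n: int, start: int, end: int) -> np.ndarray:
    """n distinct 1-based positions in [start, end], sorted ascending."""
    span = end - start + 1
    if n > span:
        raise ValueError(f"cannot place {n} distinct sites in {span} bp")
    pos = rng.choice(span, size=n, replace=False) + start
    return np.sort(pos)


def _draw_positions_excluding(
    rng: np.random.Generator, n: int, length: int, exclude: tuple[int, int] | None
) -> np.ndarray:
    """n distinct positions in [1, length] outside ``exclude``, sorted.

    Background loci are kept out of inversion spans: within a span,
    recombination suppression structures every locus by arrangement, so a
    karyotype-independent site inside the span would be unrealistic.
    """
    if exclude is None:
        return _draw_positions(rng, n, 1, length)
    lo, hi = exclude
    avail = length - (hi - lo + 1)
    if n > avail:
        raise ValueError(f"cannot place {n} sites in {avail} bp outside the span")
    raw = np.sort(rng.choice(avail, size=n, replace=False)) + 1
    return np.where(raw < lo, raw, raw + (hi - lo + 1))


def simulate_cohort(config: SimConfig) -> tuple[GenotypeMatrix, SimTruth]:
    """Generate a cohort of diploid genotypes plus its ground truth.

    Background sites: ancestral frequency ~ Uniform(0.05, 0.95); IND
    frequencies drift directly off the root, SEA and AUS+NG drift off a
    shared internal node; genotypes ~ Binomial(2, p_lineage).

    Inversion sites: each individual carries K ~ Binomial(2, q[lineage])
    inverted arrangements; its two haplotypes are drawn independently from
    the arrangement-specific allele pools, so recombination between
    arrangements is suppressed by construction.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    lineages = [l for l in config.n_per_lineage if config.n_per_lineage[l] > 0]
    sample_lineage = np.concatenate(
        [np.repeat(l, config.n_per_lineage[l]) for l in lineages]
    )
    n_total = len(sample_lineage)
    samples = [f"{l}_{i:03d}" for l in lineages for i in range(config.n_per_lineage[l])]

    chrom_names = [c for c, _ in config.chromosomes]
    chrom_len = dict(config.chromosomes)
    inv_by_chrom = {inv.chromosome: inv for inv in config.inversions}

    # --- background sites, spread evenly over chromosomes by length ---
    lengths = np.array([chrom_len[c] for c in chrom_names], dtype=float)
    n_bg = (lengths / lengths.sum() * config.n_background_snps).astype(int)
    n_bg[0] += config.n_background_snps - n_bg.sum()

    site_rows: list[pd.DataFrame] = []
    dosage_cols: list[np.ndarray] = []
    truth_fixed: dict[str, np.ndarray] = {}
    truth_pools: dict[str, pd.DataFrame] = {}
    karyo_rows = []

    # karyotypes drawn once per inversion, shared by every site of the locus
    karyotype: dict[str, np.ndarray] = {}
    for inv in config.inversions:
        q = np.array([inv.inverted_freq[l] for l in sample_lineage])
        karyotype[inv.chromosome] = rng.binomial(2, q)
        for s, l, k in zip(samples, sample_lineage, karyotype[inv.chromosome]):
            karyo_rows.append((s, l, inv.chromosome, int(k)))

    for ci, chrom in enumerate(chrom_names):
        exclude = inv_by_chrom[chrom].span if chrom in inv_by_chrom else None
        bg_pos = _draw_positions_excluding(rng, n_bg[ci], chrom_len[chrom], exclude)
        p_root = rng.uniform(0.05, 0.95, size=n_bg[ci])
        p_mid = _balding_nichols(rng, p_root, config.shared_branch_F)
        p_lin = {}
        for l in lineages:
            anc = p_root if l == "IND" else p_mid
            p_lin[l] = _balding_nichols(rng, anc, config.background_F[l])
        p_sample = np.stack([p_lin[l] for l in sample_lineage])  # n_total x n_bg
        bg_dosage = rng.binomial(2, p_sample).astype(float)

        rows = pd.DataFrame(
            {"chrom": chrom, "pos": bg_pos, "ref": "A", "alt": "T"},
            columns=SITE_COLUMNS,
        )

        if chrom in inv_by_chrom:
            inv = inv_by_chrom[chrom]
            start, end = inv.span
            inv_pos = _draw_positions(rng, inv.n_sites, start, end)

            n_fixed = int(round(inv.fixed_diff_fraction * inv.n_sites))
            is_fixed = np.zeros(inv.n_sites, dtype=bool)
            is_fixed[rng.choice(inv.n_sites, size=n_fixed, replace=False)] = True

            anc_pool = np.empty(inv.n_sites)
            inv_pool = np.empty(inv.n_sites)
            anc_pool[is_fixed] = 0.0
            inv_pool[is_fixed] = 1.0
            n_var = inv.n_sites - n_fixed
            p0 = rng.uniform(0.05, 0.95, size=n_var)
            anc_pool[~is_fixed] = _balding_nichols(rng, p0, inv.arrangement_divergence)
            drifted = _balding_nichols(rng, p0, inv.arrangement_divergence)
            inv_pool[~is_fixed] = _balding_nichols(rng, drifted, inv.inverted_pool_F)

            K = karyotype[chrom]  # per-individual inverted-arrangement count
            # haplotype 1 is inverted iff K==2, or K==1 (one of each);
            # haplotype 2 inverted iff K==2
            h1_freq = np.where((K >= 1)[:, None], inv_pool[None, :], anc_pool[None, :])
            h2_freq = np.where((K == 2)[:, None], inv_pool[None, :], anc_pool[None, :])
            inv_dosage = (
                rng.binomial(1, h1_freq) + rng.binomial(1, h2_freq)
            ).astype(float)

            truth_fixed[chrom] = inv_pos[is_fixed]
            truth_pools[chrom] = pd.DataFrame(
                {"pos": inv_pos, "anc_freq": anc_pool, "inv_freq": inv_pool}
            )

            inv_rows = pd.DataFrame(
                {"chrom": chrom, "pos": inv_pos, "ref": "A", "alt": "T"},
                columns=SITE_COLUMNS,
            )
            rows = pd.concat([rows, inv_rows], ignore_index=True)
            chrom_dosage = np.concatenate([bg_dosage, inv_dosage], axis=1)
        else:
            chrom_dosage = bg_dosage

        order = np.argsort(rows["pos"].to_numpy(), kind="stable")
        site_rows.append(rows.iloc[order])
        dosage_cols.append(chrom_dosage[:, order])

    sites = pd.concat(site_rows, ignore_index=True)
    dosage = np.concatenate(dosage_cols, axis=1)
    # chromosome names chr1..chr5 sort lexicographically == numerically here
    order = sites.sort_values(["chrom", "pos"], kind="mergesort").index.to_numpy()
    matrix = GenotypeMatrix(samples=samples, sites=sites.iloc[order], dosage=dosage[:, order])

    truth = SimTruth(
        config=config,
        karyotypes=pd.DataFrame(
            karyo_rows, columns=["sample", "lineage", "chromosome", "karyotype"]
        ),
        spans={inv.chromosome: inv.span for inv in config.inversions},
        fixed_diff_sites=truth_fixed,
        pool_freqs=truth_pools,
    )
    return matrix, truth


def default_metadata(config: SimConfig, matrix: GenotypeMatrix) -> pd.DataFrame:
    """Sample metadata table for a simulated cohort.

    Data type assignment (WGS vs RAD) is deterministic given the config
    seed: the first ``1 - rad_sample_fraction`` of each lineage is WGS.
    Location is a per-lineage pseudo-location label (two per lineage) so
    frequency-by-location tables have something to group by.
    """
    rows = []
    counters: dict[str, int] = {}
    for s in matrix.samples:
        lineage = s.rsplit("_", 1)[0]
        i = counters.get(lineage, 0)
        counters[lineage] = i + 1
        n = config.n_per_lineage[lineage]
        n_wgs = int(round((1.0 - config.rad_sample_fraction) * n))
        data_type = "WGS" if i < n_wgs else "RAD"
        location = f"{lineage}_loc{(i % 2) + 1}"
        rows.append((s, location, lineage, data_type))
    return pd.DataFrame(rows, columns=["sample", "location", "lineage", "data_type"])


def apply_ascertainment(
    matrix: GenotypeMatrix, config: SimConfig, metadata: pd.DataFrame
) -> GenotypeMatrix:
    """Mask genotypes to emulate RAD sparsity and random missingness.

    RAD-labelled samples retain genotypes only at a seeded shared subset of
    ``rad_site_fraction`` of sites (locus-based ascertainment: all RAD
    samples share the same subset, as restriction-site sampling does);
    every sample is then masked at ``missing_rate``.  Site order is
    preserved.
    """
    config.validate()
    meta = metadata.set_index("sample")
    is_rad = np.array(
        [meta.loc[s, "data_type"] == "RAD" for s in matrix.samples], dtype=bool
    )
    if is_rad.any() and config.rad_site_fraction == 0:
        raise ValueError("rad_site_fraction = 0 with RAD samples present")

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    dosage = matrix.dosage.copy()

    if is_rad.any() and config.rad_site_fraction < 1:
        n_keep = int(round(config.rad_site_fraction * matrix.n_sites))
        keep = np.zeros(matrix.n_sites, dtype=bool)
        keep[rng.choice(matrix.n_sites, size=n_keep, replace=False)] = True
        dosage[np.ix_(is_rad, ~keep)] = np.nan

    if config.missing_rate > 0:
        mask = rng.random(dosage.shape) < config.missing_rate
        dosage[mask] = np.nan

    return GenotypeMatrix(samples=list(matrix.samples), sites=matrix.sites, dosage=dosage)


def write_truth(truth: SimTruth, path) -> None:
    """SimTruth karyotypes as a TSV (sample, lineage, chromosome, karyotype)."""
    truth.karyotypes.to_csv(path, sep="\t", index=False)


def random_gene_annotation(
    config: SimConfig,
    n_genes: int = 2_000,
    n_terms: int = 100,
    mean_terms_per_gene: float = 3.0,
    seed: int = 0,
    planted_term: str | None = None,
    planted_region: tuple[str, int, int] | None = None,
    planted_fraction: float = 0.6,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Random gene models and gene->GO assignments over the config genome.

    Genes are uniform 10 kb intervals; each gene receives a Poisson number
    of GO terms drawn uniformly from a synthetic vocabulary (GO:0000001..).
    Optionally a ``planted_term`` is attached to ``planted_fraction`` of
    the genes whose midpoint falls inside ``planted_region``, giving a
    known-enriched term for recovery tests.

    Returns (annotation, gene2go): annotation has columns
    gene/chrom/start/end, gene2go has columns gene/term.
    """
    rng = np.random.default_rng(seed)
    chrom_names = [c for c, _ in config.chromosomes]
    chrom_len = dict(config.chromosomes)
    lengths = np.array([chrom_len[c] for c in chrom_names], dtype=float)
    n_per = (lengths / lengths.sum() * n_genes).astype(int)
    n_per[0] += n_genes - n_per.sum()

    rows = []
    gid = 0
    for c, n in zip(chrom_names, n_per):
        starts = np.sort(rng.integers(1, chrom_len[c] - 10_000, size=n))
        for s in starts:
            rows.append((f"gene{gid:05d}", c, int(s), int(s + 10_000)))
            gid += 1
    ann = pd.DataFrame(rows, columns=["gene", "chrom", "start", "end"])

    vocab = [f"GO:{i:07d}" for i in range(1, n_terms + 1)]
    g2g = []
    for g in ann["gene"]:
        k = rng.poisson(mean_terms_per_gene)
        for t in rng.choice(n_terms, size=min(k, n_terms), replace=False):
            g2g.append((g, vocab[t]))

    if planted_term is not None and planted_region is not None:
        c, lo, hi = planted_region
        mid = (ann["start"] + ann["end"]) // 2
        inside = ann[(ann["chrom"] == c) & (mid >= lo) & (mid <= hi)]["gene"]
        chosen = inside[rng.random(len(inside)) < planted_fraction]
        for g in chosen:
            g2g.append((g, planted_term))

    gene2go = pd.DataFrame(g2g, columns=["gene", "term"]).drop_duplicates()
    return ann, gene2go
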