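"""End-to-end orchestration: simulate/load -> filter -> local PCA -> LD ->
karyotype -> FST -> enrichment, with per-stage TSV outputs and a manifest.

Stage parameters default to the discovery analysis's settings: 50-SNP
windows, 3 MDS axes, LD blocks at r² > 0.8, diagnostic SNPs from the top
5% of PC1 loadings, site filters at 90% presence / MAF 0.05, LD pruning
at r² 0.20 in 10 kb windows, enrichment at BH alpha 0.05 with a 10-gene
minimum.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from invscan import __version__
from invscan.enrichment import fisher_enrichment, genes_in_regions
from invscan.inversion_caller import (
    CandidateRegion,
    call_karyotypes,
    default_anchor_group,
    detect_ld_blocks,
    fst_confirm,
    frequency_by_location,
    heterozygosity_by_karyotype,
    karyotype_by_pc1,
    select_diagnostic_snps,
)
from invscan.local_pca import (
    classical_mds,
    detect_outlier_windows,
    distance_matrix,
    make_windows,
    summarize_outliers,
    window_pca,
)
from invscan.popgen_core import pairwise_r2, pca
from invscan.synthetic_data import (
    SimConfig,
    apply_ascertainment,
    default_metadata,
    simulate_cohort,
    write_truth,
)
from invscan.variant_io import (
    GenotypeMatrix,
    filter_sites,
    ld_prune,
    read_metadata,
    read_vcf,
    write_metadata,
    write_vcf,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All stage parameters plus either a simulation config or input paths."""

    sim: SimConfig | None = None
    vcf_path: str | None = None
    metadata_path: str | None = None
    annotation_path: str | None = None
    gene2go_path: str | None = None

    min_presence: float = 0.90
    min_maf: float = 0.05
    prune_r2: float = 0.20
    prune_window_bp: int = 10_000
    window_snps: int = 50
    local_pca_k: int = 2
    mds_axes: int = 3
    r2_report_min: float = 0.3
    r2_block: float = 0.8
    block_min_span_bp: int = 1_000_000
    block_max_gap_bp: int = 500_000
    top_loading_fraction: float = 0.05
    min_diagnostics: int = 10
    fst_flank_bp: int = 2_000_000
    min_genes: int = 10
    alpha: float = 0.05
    skip_enrichment: bool = False

    seed: int = 0
    out_dir: str = "results/pipeline"


@dataclass
class PipelineReport:
    """In-memory bundle of everything run_pipeline computed."""

    matrix: GenotypeMatrix
    metadata: pd.DataFrame
    truth: object | None
    pruned: GenotypeMatrix
    global_pca_var: np.ndarray
    windows: list
    mds: object
    outlier_sets: list
    outlier_summaries: dict[int, pd.DataFrame]
    regions: list[CandidateRegion]
    calls: dict[str, object]
    het_tables: dict[str, pd.DataFrame]
    fst_scans: dict[str, pd.DataFrame]
    refined_regions: dict[str, CandidateRegion | None]
    freq_tables: dict[str, pd.DataFrame]
    enrichment: pd.DataFrame | None


def _stage(name: str):
    logger.info("stage: %s", name)


def run_pipeline(config: PipelineConfig) -> PipelineReport:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # --- input: simulate or load ---
    _stage("input")
    truth = None
    if config.sim is not None:
        config.sim.seed = config.sim.seed or config.seed
        raw, truth = simulate_cohort(config.sim)
        metadata = default_metadata(config.sim, raw)
        raw = apply_ascertainment(raw, config.sim, metadata)
        write_truth(truth, out / "sim_truth.tsv")
        write_metadata(metadata, out / "metadata.tsv")
    elif config.vcf_path and config.metadata_path:
        raw = read_vcf(config.vcf_path)
        metadata = read_metadata(config.metadata_path)
    else:
        raise ValueError("config needs either a simulation config or vcf+metadata paths")
    lineages = np.array(
        [metadata.set_index("sample").loc[s, "lineage"] for s in raw.samples]
    )

    # --- site filters and pruning ---
    _stage("filter")
    filtered = filter_sites(raw, config.min_presence, config.min_maf)
    _stage("prune")
    pruned = ld_prune(filtered, config.prune_r2, config.prune_window_bp)

    # --- genome-wide PCA (pruned matrix) ---
    _stage("global_pca")
    gp = pca(pruned, k=min(2, pruned.n_samples - 1))
    pd.DataFrame(
        {
            "sample": filtered.samples,
            "PC1": gp.scores[:, 0],
            "PC2": gp.scores[:, 1] if gp.scores.shape[1] > 1 else np.nan,
        }
    ).to_csv(out / "global_pca_scores.tsv", sep="\t", index=False)

    # --- local PCA / MDS outliers (unpruned filtered matrix) ---
    _stage("local_pca")
    windows = make_windows(filtered, config.window_snps)
    summaries = [window_pca(filtered, w, k=config.local_pca_k) for w in windows]
    D = distance_matrix(summaries)
    mds = classical_mds(D, n_axes=config.mds_axes)
    pd.DataFrame(
        mds.coords, columns=[f"MDS{i+1}" for i in range(mds.coords.shape[1])]
    ).assign(window=[w.index for w in windows], chrom=[w.chrom for w in windows]).to_csv(
        out / "mds_coords.tsv", sep="\t", index=False
    )
    outlier_sets, summaries_by_axis = [], {}
    for axis in range(config.mds_axes):
        oset = detect_outlier_windows(mds, axis)
        outlier_sets.append(oset)
        summaries_by_axis[axis] = summarize_outliers(oset, windows)
        summaries_by_axis[axis].to_csv(
            out / f"mds{axis + 1}_outlier_summary.tsv", sep="\t", index=False
        )

    # chromosomes flagged by any axis feed the LD scan
    outlier_chroms: list[str] = []
    chrom_of = {w.index: w.chrom for w in windows}
    for oset in outlier_sets:
        for wi in oset.window_indices:
            c = chrom_of[wi]
            if c not in outlier_chroms:
                outlier_chroms.append(c)

    # --- LD blocks on flagged chromosomes (pruned matrix) ---
    _stage("ld_blocks")
    regions: list[CandidateRegion] = []
    all_pairs = []
    for chrom in outlier_chroms:
        idx = np.flatnonzero(pruned.sites["chrom"].to_numpy() == chrom)
        if len(idx) < 2:
            continue
        pairs = pairwise_r2(pruned, idx, r2_report_min=config.r2_report_min)
        all_pairs.append(pairs)
        blocks = detect_ld_blocks(
            pairs,
            r2_min=config.r2_block,
            min_span_bp=config.block_min_span_bp,
            max_gap_bp=config.block_max_gap_bp,
        )
        if blocks:
            regions.append(blocks[0])  # longest block per chromosome
    if all_pairs:
        pd.concat(all_pairs, ignore_index=True).drop(columns=["IDX_A", "IDX_B"]).to_csv(
            out / "ld_pairs.tsv", sep="\t", index=False
        )
    _write_regions(regions, out / "candidate_regions.bed")

    # --- karyotyping, heterozygosity, FST, frequency tables ---
    calls, het_tables, fst_scans, refined, freq_tables = {}, {}, {}, {}, {}
    for region in regions:
        key = f"{region.chrom}:{region.start}-{region.end}"
        _stage(f"karyotype {key}")
        region_pca, _clusters = karyotype_by_pc1(filtered, region)
        region_idx = filtered.sites_in(region.chrom, region.start, region.end)
        diags = select_diagnostic_snps(
            region_pca,
            region_idx,
            config.top_loading_fraction,
            min_count=config.min_diagnostics,
        )
        anchor = default_anchor_group(filtered, diags, lineages)
        call = call_karyotypes(filtered, diags, anchor, region)
        calls[key] = call
        call.to_table().to_csv(out / f"karyotypes_{region.chrom}.tsv", sep="\t", index=False)

        het_tables[key] = heterozygosity_by_karyotype(filtered, call)
        het_tables[key].to_csv(
            out / f"heterozygosity_{region.chrom}.tsv", sep="\t", index=False
        )

        subset = _balanced_homokaryotype_lineage(call, lineages)
        scan, ref = fst_confirm(
            filtered, call, flank_bp=config.fst_flank_bp, sample_subset=subset
        )
        fst_scans[key] = scan
        refined[key] = ref
        scan.to_csv(out / f"fst_scan_{region.chrom}.tsv", sep="\t", index=False)

        freq_tables[key] = frequency_by_location(call, metadata)
        freq_tables[key].to_csv(
            out / f"frequency_by_location_{region.chrom}.tsv", sep="\t", index=False
        )

    # --- enrichment (optional) ---
    enr = None
    if not config.skip_enrichment and config.annotation_path and config.gene2go_path:
        _stage("enrichment")
        ann = pd.read_csv(config.annotation_path, sep="\t")
        gene2go = pd.read_csv(config.gene2go_path, sep="\t")
        gene_sets = genes_in_regions(ann, regions)
        enr = fisher_enrichment(
            gene_sets, ann, gene2go, min_genes=config.min_genes, alpha=config.alpha
        )
        enr.to_csv(out / "enrichment.tsv", sep="\t", index=False)

    _write_manifest(config, out)
    return PipelineReport(
        matrix=filtered,
        metadata=metadata,
        truth=truth,
        pruned=pruned,
        global_pca_var=gp.explained_variance_fraction,
        windows=windows,
        mds=mds,
        outlier_sets=outlier_sets,
        outlier_summaries=summaries_by_axis,
        regions=regions,
        calls=calls,
        het_tables=het_tables,
        fst_scans=fst_scans,
        refined_regions=refined,
        freq_tables=freq_tables,
        enrichment=enr,
    )


def _balanced_homokaryotype_lineage(call, lineages: np.ndarray) -> np.ndarray | None:
    """Samples of the lineage with the most balanced AHom/RHom counts.

    Mirrors restricting the homokaryotype FST comparison to the one
    lineage actually segregating for the inversion; returns None when no
    lineage has >= 2 of each homokaryotype.
    """
    best, best_score = None, 0
    for lin in pd.unique(lineages):
        sel = np.flatnonzero(lineages == lin)
        g = call.genotype[sel]
        n_a = int((g == "AHom").sum())
        n_r = int((g == "RHom").sum())
        if n_a >= 2 and n_r >= 2 and min(n_a, n_r) > best_score:
            best, best_score = sel, min(n_a, n_r)
    return best


def _write_regions(regions: list[CandidateRegion], path: Path) -> None:
    """Candidate regions as BED (0-based half-open)."""
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start - 1}\t{r.end}\t{','.join(sorted(r.evidence))}\n")


def _write_manifest(config: PipelineConfig, out: Path) -> None:
    cfg = asdict(config)
    if cfg.get("sim") and cfg["sim"].get("inversions") is not None:
        pass  # asdict already recursed dataclasses
    manifest = {"invscan_version": __version__, "config": cfg}
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
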