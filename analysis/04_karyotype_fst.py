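"""LD-block candidate regions, PC1 karyotyping, heterozygosity by
karyotype, homokaryotype FST confirmation, and karyotype frequencies by
sampling location.

Reads results/02_filtered/ and results/03_local_pca/; writes
results/04_karyotypes/ (candidate_regions.bed, karyotypes.tsv,
heterozygosity_by_karyotype.tsv, fst_scan.tsv, refined_region.bed,
frequency_by_location.tsv).
"""

from pathlib import Path

import numpy as np
import pandas as pd

from invscan.inversion_caller import (
    call_karyotypes,
    default_anchor_group,
    detect_ld_blocks,
    fst_confirm,
    frequency_by_location,
    heterozygosity_by_karyotype,
    karyotype_by_pc1,
    select_diagnostic_snps,
)
from invscan.pipeline import _balanced_homokaryotype_lineage
from invscan.popgen_core import pairwise_r2
from invscan.variant_io import read_metadata, read_vcf

BASE = Path(__file__).resolve().parent.parent / "results"
OUT = BASE / "04_karyotypes"


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    filtered = read_vcf(BASE / "02_filtered" / "filtered.vcf")
    pruned = read_vcf(BASE / "02_filtered" / "pruned.vcf")
    metadata = read_metadata(BASE / "01_cohort" / "metadata.tsv")
    lineages = metadata.set_index("sample").loc[filtered.samples, "lineage"].to_numpy()
    outliers = pd.read_csv(BASE / "03_local_pca" / "outlier_windows.tsv", sep="\t")

    regions = []
    for chrom in outliers["chrom"].unique():
        idx = np.flatnonzero(pruned.sites["chrom"].to_numpy() == chrom)
        if len(idx) < 2:
            continue
        pairs = pairwise_r2(pruned, idx, r2_report_min=0.3)
        blocks = detect_ld_blocks(pairs, r2_min=0.8, min_span_bp=1_000_000)
        if blocks:
            regions.append(blocks[0])
    with open(OUT / "candidate_regions.bed", "w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start - 1}\t{r.end}\tld_block\n")
    print(f"{len(regions)} candidate region(s)")

    for region in regions:
        print(f"== {region.chrom}:{region.start}-{region.end} ==")
        region_pca, _ = karyotype_by_pc1(filtered, region)
        region_idx = filtered.sites_in(region.chrom, region.start, region.end)
        diags = select_diagnostic_snps(region_pca, region_idx, 0.05, min_count=10)
        anchor = default_anchor_group(filtered, diags, lineages)
        call = call_karyotypes(filtered, diags, anchor, region)
        call.to_table().to_csv(OUT / "karyotypes.tsv", sep="\t", index=False)
        print(pd.Series(call.genotype).value_counts().to_string())

        het = heterozygosity_by_karyotype(filtered, call)
        het.to_csv(OUT / "heterozygosity_by_karyotype.tsv", sep="\t", index=False)
        print(het.to_string(index=False))

        subset = _balanced_homokaryotype_lineage(call, lineages)
        scan, refined = fst_confirm(filtered, call, sample_subset=subset)
        scan.to_csv(OUT / "fst_scan.tsv", sep="\t", index=False)
        if refined is not None:
            with open(OUT / "refined_region.bed", "w") as fh:
                fh.write(
                    f"{refined.chrom}\t{refined.start - 1}\t{refined.end}\tfst_run\n"
                )
            print(f"refined span: {refined.chrom}:{refined.start}-{refined.end}")

        freq = frequency_by_location(call, metadata)
        freq.to_csv(OUT / "frequency_by_location.tsv", sep="\t", index=False)
        print(freq.to_string(index=False))


if __name__ == "__main__":
    main()
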