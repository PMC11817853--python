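"""Site filters (presence >= 0.90, MAF >= 0.05) and LD pruning
(r² <= 0.20 in 10 kb windows) on the simulated cohort.

Reads results/01_cohort/, writes results/02_filtered/ (filtered.vcf,
pruned.vcf, site_counts.tsv).
"""

from pathlib import Path

import pandas as pd

from invscan.variant_io import filter_sites, ld_prune, read_vcf, write_vcf

BASE = Path(__file__).resolve().parent.parent / "results"
OUT = BASE / "02_filtered"


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    raw = read_vcf(BASE / "01_cohort" / "cohort.vcf")
    filtered = filter_sites(raw, min_presence=0.90, min_maf=0.05)
    pruned = ld_prune(filtered, r2_max=0.20, window_bp=10_000)
    write_vcf(filtered, OUT / "filtered.vcf")
    write_vcf(pruned, OUT / "pruned.vcf")
    counts = pd.DataFrame(
        {
            "stage": ["raw", "filtered", "pruned"],
            "n_sites": [raw.n_sites, filtered.n_sites, pruned.n_sites],
        }
    )
    counts.to_csv(OUT / "site_counts.tsv", sep="\t", index=False)
    print(counts.to_string(index=False))


if __name__ == "__main__":
    main()
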