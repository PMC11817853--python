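"""Windowed local PCA, window-distance MDS, and Tukey outlier windows.

Reads results/02_filtered/filtered.vcf; writes results/03_local_pca/
(mds_coords.tsv, mds{1,2,3}_outlier_summary.tsv, outlier_windows.tsv).
"""

from pathlib import Path

import pandas as pd

from invscan.local_pca import (
    classical_mds,
    detect_outlier_windows,
    distance_matrix,
    make_windows,
    summarize_outliers,
    window_pca,
)
from invscan.variant_io import read_vcf

BASE = Path(__file__).resolve().parent.parent / "results"
OUT = BASE / "03_local_pca"


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    m = read_vcf(BASE / "02_filtered" / "filtered.vcf")
    windows = make_windows(m, window_snps=50)
    summaries = [window_pca(m, w, k=2) for w in windows]
    mds = classical_mds(distance_matrix(summaries), n_axes=3)

    pd.DataFrame(
        mds.coords, columns=["MDS1", "MDS2", "MDS3"]
    ).assign(
        window=[w.index for w in windows],
        chrom=[w.chrom for w in windows],
        bp_start=[w.bp_start for w in windows],
        bp_end=[w.bp_end for w in windows],
    ).to_csv(OUT / "mds_coords.tsv", sep="\t", index=False)

    rows = []
    for axis in range(3):
        oset = detect_outlier_windows(mds, axis)
        summary = summarize_outliers(oset, windows)
        summary.to_csv(OUT / f"mds{axis + 1}_outlier_summary.tsv", sep="\t", index=False)
        for wi in oset.window_indices:
            w = windows[wi]
            rows.append((axis + 1, w.index, w.chrom, w.bp_start, w.bp_end))
        print(f"MDS{axis + 1}: {len(oset.window_indices)} outlier windows")
        if not summary.empty:
            print(summary.to_string(index=False))
    pd.DataFrame(
        rows, columns=["axis", "window", "chrom", "bp_start", "bp_end"]
    ).to_csv(OUT / "outlier_windows.tsv", sep="\t", index=False)


if __name__ == "__main__":
    main()
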