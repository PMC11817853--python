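"""LD-block detection, PC1 karyotyping, diagnostic SNPs, karyotype calls,
heterozygosity-by-class, FST confirmation, and location frequencies."""

import numpy as np
import pandas as pd
import pytest

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
from invscan.popgen_core import pairwise_r2, pca

from conftest import make_matrix


def pair_frame(rows):
    """rows: (pos_a, pos_b, r2) on one chromosome."""
    return pd.DataFrame(
        {
            "CHR_A": "chr1",
            "POS_A": [r[0] for r in rows],
            "CHR_B": "chr1",
            "POS_B": [r[1] for r in rows],
            "R2": [r[2] for r in rows],
        }
    )


@pytest.fixture(scope="module")
def called_cohort(default_cohort):
    """Region call on the full (pre-ascertainment) default cohort."""
    cfg, m, _, metadata, truth = default_cohort
    spec = cfg.inversions[0]
    region = CandidateRegion(
        chrom=spec.chromosome, start=spec.span[0], end=spec.span[1]
    )
    res, clusters = karyotype_by_pc1(m, region)
    idx = m.sites_in(region.chrom, region.start, region.end)
    diags = select_diagnostic_snps(res, idx, top_fraction=0.05, min_count=10)
    lineages = metadata.set_index("sample").loc[m.samples, "lineage"].to_numpy()
    anchor = default_anchor_group(m, diags, lineages)
    call = call_karyotypes(m, diags, anchor, region)
    return cfg, m, metadata, truth, region, res, clusters, diags, call


class TestDetectLdBlocks:
    def test_merged_block_spans_constructed_pairs(self):
        rows = [
            (5_000_000, 9_000_000, 0.95),
            (9_200_000, 15_000_000, 0.9),
            (15_100_000, 22_000_000, 0.85),
            (24_000_000, 24_050_000, 0.99),  # isolated pair, tiny span
        ]
        blocks = detect_ld_blocks(pair_frame(rows), r2_min=0.8, min_span_bp=1_000_000)
        assert len(blocks) == 1
        assert (blocks[0].start, blocks[0].end) == (5_000_000, 22_000_000)
        assert "ld_block" in blocks[0].evidence

    def test_gap_larger_than_max_splits_block(self):
        rows = [
            (1_000_000, 3_000_000, 0.9),
            (4_000_000, 6_000_000, 0.9),  # 1 Mb gap > 500 kb default
        ]
        blocks = detect_ld_blocks(pair_frame(rows), r2_min=0.8)
        assert len(blocks) == 2
        assert blocks[0].span_bp >= blocks[1].span_bp

    def test_weak_pairs_yield_nothing(self):
        rows = [(1_000_000, 5_000_000, 0.5), (2_000_000, 9_000_000, 0.79)]
        assert detect_ld_blocks(pair_frame(rows), r2_min=0.8) == []

    def test_null_cohort_has_no_block(self, small_structured_cohort):
        # filtered + pruned as in the pipeline: population structure alone
        # creates long-range LD among unpruned rare/differentiated sites
        from invscan.variant_io import filter_sites, ld_prune

        _, m, _ = small_structured_cohort
        pruned = ld_prune(filter_sites(m, 0.9, 0.05), 0.2, 10_000)
        pairs = pairwise_r2(pruned, r2_report_min=0.3)
        blocks = detect_ld_blocks(pairs, r2_min=0.8, min_span_bp=1_000_000)
        assert blocks == []

    def test_mixed_chromosomes_rejected(self):
        bad = pair_frame([(1, 2, 0.9)])
        bad.loc[0, "CHR_B"] = "chr2"
        with pytest.raises(ValueError, match="one chromosome"):
            detect_ld_blocks(bad)


class TestKaryotypeByPc1:
    def test_clusters_recover_simulated_karyotypes(self, called_cohort):
        cfg, _, _, truth, _, _, clusters, _, _ = called_cohort
        K = truth.karyotype_vector(cfg.inversions[0].chromosome)
        # clusters are ordered along PC1; orientation may be flipped
        agree = max((clusters == K).mean(), (clusters == 2 - K).mean())
        assert agree >= 0.98

    def test_sample_permutation_equivariance(self, called_cohort):
        _, m, _, _, region, _, clusters, _, _ = called_cohort
        perm = np.random.default_rng(0).permutation(m.n_samples)
        m_p = m.take_samples(perm)
        _, clusters_p = karyotype_by_pc1(m_p, CandidateRegion(
            chrom=region.chrom, start=region.start, end=region.end))
        expected = clusters[perm]
        agree = max((clusters_p == expected).mean(),
                    (clusters_p == 2 - expected).mean())
        assert agree >= 0.98

    def test_too_few_polymorphic_sites_rejected(self):
        d = np.tile(np.array([[0.0], [1.0], [2.0], [1.0]]), (1, 10))
        m = make_matrix(d)
        with pytest.raises(ValueError, match="polymorphic"):
            karyotype_by_pc1(m, CandidateRegion("chr1", 1, 5_000), min_sites=20)


class TestSelectDiagnosticSnps:
    def _fake_pca(self, loadings_pc1):
        from invscan.popgen_core import PCAResult

        return PCAResult(
            scores=np.zeros((2, 1)),
            loadings=np.asarray(loadings_pc1, dtype=float)[:, None],
            explained_variance_fraction=np.array([1.0]),
        )

    def test_fraction_of_100_sites_is_5(self):
        rng = np.random.default_rng(0)
        res = self._fake_pca(rng.normal(size=100))
        out = select_diagnostic_snps(res, np.arange(100), top_fraction=0.05)
        assert len(out) == 5
        load = np.abs(res.loadings[:, 0])
        assert set(out) == set(np.argsort(-load)[:5])

    def test_fraction_one_returns_all(self):
        res = self._fake_pca(np.linspace(-1, 1, 30))
        out = select_diagnostic_snps(res, np.arange(30), top_fraction=1.0)
        assert len(out) == 30

    def test_min_count_floor_applies(self):
        res = self._fake_pca(np.linspace(-1, 1, 40))
        out = select_diagnostic_snps(res, np.arange(40), 0.05, min_count=10)
        assert len(out) == 10

    def test_diagnostics_enriched_for_fixed_differences(self, called_cohort):
        cfg, m, _, truth, _, _, _, diags, _ = called_cohort
        chrom = cfg.inversions[0].chromosome
        fixed = set(truth.fixed_diff_sites[chrom])
        pos = m.sites["pos"].to_numpy()[diags]
        assert np.isin(pos, list(fixed)).mean() >= 0.8


class TestCallKaryotypes:
    def region(self):
        return CandidateRegion("chr1", 1, 10_000)

    def test_threshold_boundaries(self):
        # 10 diagnostics; anchor sample fixes polarity (all zeros).
        # mean dosages: 0.4 -> AHom, exactly 0.5 -> Het, 1.5 -> Het, 1.6 -> RHom
        rows = [
            np.zeros(10),                       # anchor, mean 0 -> AHom
            np.array([1] * 4 + [0] * 6, float),  # 0.4 -> AHom
            np.array([1] * 5 + [0] * 5, float),  # 0.5 -> Het (inclusive)
            np.array([2] * 5 + [1] * 5, float),  # 1.5 -> Het (inclusive)
            np.array([2] * 6 + [1] * 4, float),  # 1.6 -> RHom
        ]
        m = make_matrix(np.vstack(rows))
        call = call_karyotypes(m, np.arange(10), np.array([0]), self.region())
        assert list(call.genotype) == ["AHom", "AHom", "Het", "Het", "RHom"]
        assert call.mean_dosage[2] == pytest.approx(0.5)

    def test_global_polarity_flip_invariance(self):
        rng = np.random.default_rng(1)
        d = rng.integers(0, 3, size=(20, 12)).astype(float)
        d[:5] = 0.0  # anchor block homozygous ancestral
        m = make_matrix(d)
        call = call_karyotypes(m, np.arange(12), np.arange(5), self.region())
        flipped = call_karyotypes(
            make_matrix(2.0 - d), np.arange(12), np.arange(5), self.region()
        )
        assert list(call.genotype) == list(flipped.genotype)
        assert np.allclose(call.mean_dosage, flipped.mean_dosage, equal_nan=True)

    def test_sparse_samples_unassigned(self):
        d = np.zeros((3, 10))
        d[2, :6] = np.nan  # only 4 observed < min_observed 5
        m = make_matrix(d)
        call = call_karyotypes(m, np.arange(10), np.array([0]), self.region())
        assert call.genotype[2] == "unassigned"
        assert np.isnan(call.mean_dosage[2])

    def test_empty_inputs_rejected(self):
        m = make_matrix(np.zeros((3, 4)))
        with pytest.raises(ValueError, match="diagnostic"):
            call_karyotypes(m, np.array([], dtype=int), np.array([0]), self.region())
        with pytest.raises(ValueError, match="anchor"):
            call_karyotypes(m, np.arange(4), np.array([], dtype=int), self.region())

    def test_simulated_calls_match_truth(self, called_cohort):
        cfg, _, _, truth, _, _, _, _, call = called_cohort
        K = truth.karyotype_vector(cfg.inversions[0].chromosome)
        label_of = {0: "AHom", 1: "Het", 2: "RHom"}
        expected = np.array([label_of[k] for k in K])
        assigned = call.genotype != "unassigned"
        assert assigned.mean() > 0.95
        assert (call.genotype[assigned] == expected[assigned]).mean() >= 0.98


class TestHeterozygosityByKaryotype:
    def test_het_class_exceeds_homokaryotypes(self, called_cohort):
        cfg, m, _, _, _, _, _, _, call = called_cohort
        table = heterozygosity_by_karyotype(m, call).set_index("genotype")
        assert table.loc["Het", "median"] > table.loc["AHom", "median"]
        assert table.loc["Het", "median"] > table.loc["RHom", "median"]
        assert table.loc["Het", "q1"] >= table.loc["AHom", "q3"]

    def test_single_class_table(self):
        d = np.zeros((4, 30))
        m = make_matrix(d)
        region = CandidateRegion("chr1", 1, 10_000)
        call = call_karyotypes(m, np.arange(30), np.array([0]), region)
        table = heterozygosity_by_karyotype(m, call)
        assert list(table["genotype"]) == ["AHom"]
        assert table["n"].iloc[0] == 4


class TestFstConfirm:
    def test_recovers_simulated_span(self, called_cohort):
        # restrict to the one lineage segregating for both homokaryotypes,
        # as the pipeline does: with lineages mixed, background lineage
        # differentiation inflates flank FST and shrinks the detected run
        cfg, m, metadata, _, _, _, _, _, call = called_cohort
        lineages = metadata.set_index("sample").loc[m.samples, "lineage"].to_numpy()
        from invscan.pipeline import _balanced_homokaryotype_lineage

        subset = _balanced_homokaryotype_lineage(call, lineages)
        scan, refined = fst_confirm(m, call, sample_subset=subset)
        span = cfg.inversions[0].span
        assert refined is not None
        assert "fst_elevated" in call.region.evidence
        # refined endpoints within 10% of the span length of the truth
        tol = 0.1 * (span[1] - span[0])
        assert abs(refined.start - span[0]) <= tol
        assert abs(refined.end - span[1]) <= tol
        inside = scan[(scan["pos"] >= span[0]) & (scan["pos"] <= span[1])]
        flank = scan[(scan["pos"] < span[0]) | (scan["pos"] > span[1])]
        assert inside["fst"].mean() > 10 * max(flank["fst"].mean(), 0.01)

    def test_null_split_finds_nothing(self, small_structured_cohort):
        _, m, _ = small_structured_cohort
        region = CandidateRegion("chr1", 3_000_000, 6_000_000)
        # arbitrary within-lineage split labelled as homokaryotypes
        genotype = np.array(
            (["AHom", "RHom"] * (m.n_samples // 2 + 1))[: m.n_samples], dtype=object
        )
        from invscan.inversion_caller import KaryotypeCall

        call = KaryotypeCall(
            region=region,
            samples=list(m.samples),
            genotype=genotype,
            mean_dosage=np.zeros(m.n_samples),
            n_diagnostics_observed=np.full(m.n_samples, 10),
            diagnostic_sites=np.arange(5),
        )
        _, refined = fst_confirm(m, call)
        assert "fst_elevated" not in region.evidence
        assert refined is None or refined.span_bp < 1_000_000

    def test_too_few_homokaryotypes_skips(self):
        m = make_matrix(np.zeros((4, 10)))
        region = CandidateRegion("chr1", 1, 500)
        call = call_karyotypes(m, np.arange(10), np.array([0]), region)
        scan, refined = fst_confirm(m, call)  # no RHom samples at all
        assert scan.empty and refined is None


class TestFrequencyByLocation:
    def test_counts_and_frequencies(self, called_cohort):
        cfg, _, metadata, truth, _, _, _, _, call = called_cohort
        freq = frequency_by_location(call, metadata).set_index("location")
        spec = cfg.inversions[0]
        for lineage, q in spec.inverted_freq.items():
            locs = [f"{lineage}_loc1", f"{lineage}_loc2"]
            vals = freq.loc[[l for l in locs if l in freq.index], "inverted_freq"]
            if q == 0.0:
                assert (vals == 0.0).all()
            elif q == 1.0:
                assert (vals == 1.0).all()
            else:
                assert ((vals > 0.2) & (vals < 0.8)).all()

    def test_all_rhom_gives_frequency_one(self):
        call_samples = ["a", "b", "c"]
        from invscan.inversion_caller import KaryotypeCall

        call = KaryotypeCall(
            region=CandidateRegion("chr1", 1, 100),
            samples=call_samples,
            genotype=np.array(["RHom", "RHom", "unassigned"], dtype=object),
            mean_dosage=np.array([2.0, 2.0, np.nan]),
            n_diagnostics_observed=np.array([10, 10, 0]),
            diagnostic_sites=np.arange(3),
        )
        meta = pd.DataFrame(
            {
                "sample": call_samples,
                "location": ["x", "x", "y"],
                "lineage": "L",
                "data_type": "WGS",
            }
        )
        freq = frequency_by_location(call, meta)
        assert list(freq["location"]) == ["x"]  # y has no assigned samples
        assert freq["inverted_freq"].iloc[0] == 1.0
        assert freq["RHom"].iloc[0] == 2
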