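"""Windowing, window-PCA summaries, window distances, classical MDS, and
Tukey outlier windows, each against an explicit brute-force oracle."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

from invscan.local_pca import (
    MDSResult,
    classical_mds,
    detect_outlier_windows,
    distance_matrix,
    make_windows,
    summarize_outliers,
    tukey_hinges,
    window_distance,
    window_pca,
)

from conftest import make_matrix


def random_window_summaries(n_windows, n_samples=30, window_snps=20, seed=0, k=2):
    rng = np.random.default_rng(seed)
    d = rng.integers(0, 3, size=(n_samples, n_windows * window_snps)).astype(float)
    m = make_matrix(d)
    windows = make_windows(m, window_snps)
    return m, windows, [window_pca(m, w, k=k) for w in windows]


class TestMakeWindows:
    def test_remainder_discarded(self):
        m = make_matrix(np.random.default_rng(0).integers(0, 3, (4, 120)).astype(float))
        wins = make_windows(m, 50)
        assert len(wins) == 2
        assert wins[0].site_start == 0 and wins[0].site_stop == 50
        assert wins[1].site_start == 50 and wins[1].site_stop == 100

    def test_exact_fit_single_window(self):
        m = make_matrix(np.random.default_rng(0).integers(0, 3, (4, 50)).astype(float))
        assert len(make_windows(m, 50)) == 1

    def test_windows_never_span_chromosomes(self):
        rng = np.random.default_rng(1)
        d = rng.integers(0, 3, size=(4, 120)).astype(float)
        sites = pd.DataFrame(
            {
                "chrom": ["chr1"] * 60 + ["chr2"] * 60,
                "pos": list(range(1, 61)) * 2,
                "ref": "A",
                "alt": "T",
            }
        )
        from invscan.variant_io import GenotypeMatrix

        m = GenotypeMatrix(samples=[f"s{i}" for i in range(4)], sites=sites, dosage=d)
        wins = make_windows(m, 50)
        assert len(wins) == 2
        assert {w.chrom for w in wins} == {"chr1", "chr2"}


class TestWindowPCA:
    def test_deterministic_for_identical_windows(self):
        m, wins, summ = random_window_summaries(1, seed=3)
        again = window_pca(m, wins[0], k=2)
        assert np.array_equal(summ[0].eigenvalues, again.eigenvalues)
        assert np.array_equal(summ[0].eigenvectors, again.eigenvectors)

    def test_rank_deficient_window(self):
        d = np.tile(np.array([[0.0], [1.0], [2.0], [1.0]]), (1, 20))
        m = make_matrix(d)
        w = make_windows(m, 20)[0]
        s = window_pca(m, w, k=3)
        assert s.eigenvalues[0] > 0
        assert np.all(s.eigenvalues[1:] < 1e-10)

    def test_matches_dense_eigendecomposition(self):
        from invscan.popgen_core import impute_center

        m, wins, summ = random_window_summaries(1, seed=8)
        X = impute_center(m.dosage[:, wins[0].site_indices])
        C = X @ X.T / (X.shape[1] - 1)
        vals = np.sort(np.linalg.eigvalsh(C))[::-1]
        assert np.allclose(summ[0].eigenvalues, vals[:2], atol=1e-8)
        for j in range(2):
            v = summ[0].eigenvectors[:, j]
            assert np.linalg.norm(C @ v - summ[0].eigenvalues[j] * v) < 1e-8


class TestWindowDistance:
    def test_identity_and_symmetry(self):
        _, _, summ = random_window_summaries(4, seed=2)
        # self-distance is cancellation noise: sqrt of ~1e-16 residuals
        assert window_distance(summ[0], summ[0]) < 1e-6
        for a in summ:
            for b in summ:
                assert window_distance(a, b) == pytest.approx(
                    window_distance(b, a), abs=1e-12
                )

    def test_matches_explicit_matrix_oracle_100_windows(self):
        _, _, summ = random_window_summaries(100, seed=7)
        rng = np.random.default_rng(0)
        for _ in range(150):
            a, b = summ[rng.integers(100)], summ[rng.integers(100)]
            explicit = np.linalg.norm(
                a.approx_covariance() - b.approx_covariance(), "fro"
            )
            assert window_distance(a, b) == pytest.approx(explicit, abs=1e-6)

    def test_distance_matrix_properties(self):
        _, _, summ = random_window_summaries(25, seed=5)
        D = distance_matrix(summ)
        assert np.allclose(D, D.T, atol=1e-12)
        assert np.allclose(np.diag(D), 0.0, atol=1e-6)
        assert (D >= 0).all()
        rng = np.random.default_rng(1)
        for _ in range(200):  # triangle inequality on sampled triples
            i, j, k = rng.integers(25, size=3)
            assert D[i, j] <= D[i, k] + D[k, j] + 1e-8
        # pairwise entries agree with the scalar function
        for i in range(0, 25, 5):
            for j in range(0, 25, 5):
                assert D[i, j] == pytest.approx(
                    window_distance(summ[i], summ[j]), abs=1e-6
                )


class TestClassicalMDS:
    def test_collinear_three_points(self):
        D = np.array([[0.0, 1.0, 2.0], [1.0, 0.0, 1.0], [2.0, 1.0, 0.0]])
        res = classical_mds(D, n_axes=1)
        emb = squareform(pdist(res.coords))
        assert np.abs(emb - D).max() < 1e-10

    def test_zero_distances_give_zero_coordinates(self):
        res = classical_mds(np.zeros((6, 6)), n_axes=3)
        assert np.all(res.coords == 0)

    def test_euclidean_round_trip(self):
        rng = np.random.default_rng(11)
        pts = rng.normal(size=(40, 3))
        D = squareform(pdist(pts))
        res = classical_mds(D, n_axes=3)
        emb = squareform(pdist(res.coords))
        assert np.abs(emb - D).max() < 1e-8

    def test_window_permutation_permutes_rows(self):
        _, _, summ = random_window_summaries(12, seed=9)
        D = distance_matrix(summ)
        perm = np.random.default_rng(2).permutation(12)
        res = classical_mds(D, n_axes=3)
        res_p = classical_mds(D[np.ix_(perm, perm)], n_axes=3)
        for j in range(3):
            col, col_p = res.coords[perm, j], res_p.coords[:, j]
            assert np.allclose(col, col_p, atol=1e-8) or np.allclose(
                col, -col_p, atol=1e-8
            )

    def test_input_validation(self):
        with pytest.raises(ValueError, match="square"):
            classical_mds(np.zeros((3, 4)))
        bad = np.array([[0.0, 1.0], [2.0, 0.0]])
        with pytest.raises(ValueError, match="symmetric"):
            classical_mds(bad)


class TestOutlierWindows:
    def test_hinge_arithmetic_by_hand(self):
        # {1..9, 100}: hinges 3 and 8, fences (-4.5, 15.5) -> outlier {100}
        vals = np.array(list(range(1, 10)) + [100], dtype=float)
        assert tukey_hinges(vals) == (3.0, 8.0)
        mds = MDSResult(
            coords=vals[:, None], eigenvalues=np.array([1.0]),
            window_indices=np.arange(10),
        )
        out = detect_outlier_windows(mds, axis=0)
        assert list(out.window_indices) == [9]
        assert out.fences == (-4.5, 15.5)

    def test_symmetric_values_no_outliers(self):
        vals = np.linspace(-1, 1, 20)
        mds = MDSResult(vals[:, None], np.array([1.0]), np.arange(20))
        assert len(detect_outlier_windows(mds, 0).window_indices) == 0

    def test_outliers_lie_outside_fences(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(size=60)
        vals[:4] += 10
        mds = MDSResult(vals[:, None], np.array([1.0]), np.arange(60))
        out = detect_outlier_windows(mds, 0)
        lo, hi = out.fences
        assert all(vals[i] < lo or vals[i] > hi for i in out.window_indices)


class TestSummarizeOutliers:
    @pytest.mark.parametrize(
        "per_chrom,expect_top",
        [
            ({"c05": 9, "other": 16}, 36.0),
            ({"c03": 42, "other": 44}, 48.8),
            ({"c20": 47, "other": 69}, 40.5),
        ],
    )
    def test_percentage_formatting(self, per_chrom, expect_top):
        windows, outliers = [], []
        from invscan.local_pca import OutlierSet, Window

        i = 0
        for chrom, n in per_chrom.items():
            for _ in range(n):
                windows.append(
                    Window(index=i, chrom=chrom, site_start=0, site_stop=1,
                           bp_start=1, bp_end=2)
                )
                outliers.append(i)
                i += 1
        oset = OutlierSet(axis=0, window_indices=np.array(outliers), fences=(0, 0))
        summary = summarize_outliers(oset, windows)
        top_chrom = next(c for c in per_chrom if c != "other")
        row = summary[summary["chrom"] == top_chrom].iloc[0]
        assert row["pct_of_axis"] == expect_top

    def test_zero_outliers_empty_summary(self):
        from invscan.local_pca import OutlierSet

        oset = OutlierSet(axis=0, window_indices=np.array([], dtype=int), fences=(0, 0))
        assert summarize_outliers(oset, []).empty
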