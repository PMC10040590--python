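"""Genomic relationship and Gaussian kernel construction."""

import numpy as np
import pytest

from gspred import (
    GenotypeMatrix,
    KernelMatrix,
    gaussian_kernel,
    genomic_relationship,
    kernel_averaging_list,
    standardize_markers,
)
from gspred.genotypes import StandardizedMarkers


def _sm(values):
    values = np.asarray(values, dtype=float)
    n, m = values.shape
    return StandardizedMarkers(
        values,
        [f"L{i}" for i in range(n)],
        [f"M{j}" for j in range(m)],
        np.zeros(m),
        np.ones(m),
    )


def _random_W(rng, n, m):
    vals = rng.binomial(2, rng.uniform(0.1, 0.5, m), size=(n, m)).astype(float)
    keep = vals.std(axis=0) > 0
    geno = GenotypeMatrix(
        vals[:, keep], [f"L{i}" for i in range(n)],
        [f"M{j}" for j in range(int(keep.sum()))],
    )
    return standardize_markers(geno)


class TestGenomicRelationship:
    def test_small_matrix_product(self):
        W = _sm([[1, -1], [-1, 1], [0, 0]])
        G = genomic_relationship(W)
        expected = np.array([[1, -1, 0], [-1, 1, 0], [0, 0, 0]], dtype=float)
        assert np.allclose(G.values, expected)
        assert G.kind == "G"

    def test_identical_lines_have_equal_entries(self):
        W = _sm([[1.0, -0.5], [1.0, -0.5], [-2.0, 1.0]])
        G = genomic_relationship(W).values
        assert G[0, 1] == pytest.approx(G[0, 0])
        assert G[0, 1] == pytest.approx(G[1, 1])

    def test_mean_diagonal_identity(self, rng):
        # for sample-standardized columns, mean(diag(G)) = (n-1)/n exactly
        W = _random_W(rng, 50, 500)
        G = genomic_relationship(W)
        n = W.n_lines
        assert np.mean(np.diag(G.values)) == pytest.approx((n - 1) / n, abs=1e-10)

    def test_duplicated_panel_block_structure(self, rng):
        W = _random_W(rng, 20, 100)
        dup = StandardizedMarkers(
            np.vstack([W.values, W.values]),
            [f"A{i}" for i in range(W.n_lines)] + [f"B{i}" for i in range(W.n_lines)],
            W.marker_ids, W.column_means, W.column_sds,
        )
        G = genomic_relationship(dup).values
        n = W.n_lines
        assert np.allclose(G[:n, :n], G[n:, n:])
        assert np.allclose(G[:n, :n], G[:n, n:])

    def test_psd_within_tolerance(self, rng):
        W = _random_W(rng, 60, 200)
        G = genomic_relationship(W)
        vals, _ = G.eigendecompose()  # raises if indefinite
        assert vals.min() >= 0

    def test_hwe_and_sample_standardization_agree(self, rng):
        # Hardy-Weinberg genotypes: 2p-centered and sample-centered G entries
        # correlate almost perfectly at large m
        n, m = 80, 2000
        p = rng.uniform(0.1, 0.5, m)
        vals = rng.binomial(2, p, size=(n, m)).astype(float)
        keep = vals.std(axis=0) > 0
        geno = GenotypeMatrix(
            vals[:, keep], [f"L{i}" for i in range(n)],
            [f"M{j}" for j in range(int(keep.sum()))],
        )
        G1 = genomic_relationship(standardize_markers(geno)).values
        G2 = genomic_relationship(
            standardize_markers(geno, use_allele_freqs=True)
        ).values
        iu = np.triu_indices(n)
        assert np.corrcoef(G1[iu], G2[iu])[0, 1] > 0.99


class TestGaussianKernel:
    def test_zero_bandwidth_all_ones(self):
        W = _sm([[1, 0], [0, 1], [2, -1]])
        GK = gaussian_kernel(W, 0.0)
        assert np.allclose(GK.values, 1.0)

    def test_identical_lines_entry_one(self):
        W = _sm([[1.0, 2.0], [1.0, 2.0], [0.0, 0.0]])
        GK = gaussian_kernel(W, 0.7)
        assert GK.values[0, 1] == pytest.approx(1.0)

    def test_closed_form_entry(self):
        # two lines at squared distance 1, theta = 0.2 -> exp(-0.2)
        W = _sm([[0.0], [1.0]])
        GK = gaussian_kernel(W, 0.2)
        assert GK.values[0, 1] == pytest.approx(np.exp(-0.2), abs=1e-12)

    def test_negative_bandwidth_rejected(self):
        with pytest.raises(ValueError, match="theta"):
            gaussian_kernel(_sm([[0.0], [1.0]]), -0.1)

    def test_entries_in_unit_interval_with_unit_diagonal(self, rng):
        W = _random_W(rng, 30, 100)
        GK = gaussian_kernel(W, 1.2).values
        assert np.all(GK > 0) and np.all(GK <= 1)
        assert np.allclose(np.diag(GK), 1.0)

    def test_eigenvalues_nonnegative(self, rng):
        W = _random_W(rng, 100, 150)
        GK = gaussian_kernel(W, 0.2)
        vals, _ = GK.eigendecompose()
        assert vals.min() >= 0


class TestKernelAveraging:
    def test_default_bandwidths(self, rng):
        W = _random_W(rng, 20, 50)
        ks = kernel_averaging_list(W)
        assert [k.bandwidth for k in ks] == [0.2, 1.2]
        assert all(k.kind == "GK" for k in ks)

    def test_empty_bandwidth_list_rejected(self, rng):
        with pytest.raises(ValueError, match="non-empty"):
            kernel_averaging_list(_random_W(rng, 10, 20), ())

    def test_entrywise_monotone_in_bandwidth(self, rng):
        W = _random_W(rng, 25, 60)
        k_small, k_large = kernel_averaging_list(W, (0.2, 1.2))
        off = ~np.eye(W.n_lines, dtype=bool)
        assert np.all(k_small.values[off] >= k_large.values[off])


class TestKernelMatrix:
    def test_asymmetric_rejected(self):
        M = np.array([[1.0, 0.5], [0.2, 1.0]])
        with pytest.raises(ValueError, match="symmetric"):
            KernelMatrix(M, ["a", "b"])

    def test_indefinite_rejected_on_eigendecompose(self):
        M = np.array([[1.0, 2.0], [2.0, 1.0]])  # eigenvalues 3, -1
        km = KernelMatrix(M, ["a", "b"])
        with pytest.raises(ValueError, match="positive semi-definite"):
            km.eigendecompose()
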