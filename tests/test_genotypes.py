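"""Marker QC, standardization and the genotype container."""

import numpy as np
import pytest

from gspred import (
    EmptyPanelError,
    GenotypeMatrix,
    apply_marker_qc,
    standardize_markers,
)


def _gm(values, line_prefix="L", marker_prefix="M"):
    values = np.asarray(values, dtype=float)
    return GenotypeMatrix(
        values,
        [f"{line_prefix}{i}" for i in range(values.shape[0])],
        [f"{marker_prefix}{j}" for j in range(values.shape[1])],
    )


class TestContainer:
    def test_rejects_invalid_codes(self):
        with pytest.raises(ValueError, match="invalid gene content"):
            _gm([[0, 3], [1, 2]])

    def test_rejects_duplicate_ids(self):
        with pytest.raises(ValueError, match="duplicate line_ids"):
            GenotypeMatrix(np.zeros((2, 1)), ["A", "A"], ["M1"])

    def test_allele_freqs_exclude_missing(self):
        g = _gm([[0, 2], [2, np.nan], [1, 2]])
        assert np.allclose(g.allele_freqs, [0.5, 1.0])

    def test_mean_imputation_fills_column_mean(self):
        g = _gm([[0, 2], [2, np.nan], [1, 0]])
        imp = g.imputed()
        assert imp.values[1, 1] == pytest.approx(1.0)
        assert not np.isnan(imp.values).any()


class TestMarkerQC:
    def test_low_maf_column_removed(self):
        # 50 lines, column 0 has allele frequency 0.03 < 0.05
        n = 50
        vals = np.ones((n, 2))
        vals[:, 0] = 0.0
        vals[:3, 0] = 1.0  # freq = 3/100 = 0.03
        clean, rep = apply_marker_qc(_gm(vals), maf_min=0.05, het_max=1.0, r2_max=1.0)
        assert rep.removed_maf == ["M0"]
        assert clean.marker_ids == ["M1"]

    def test_clean_panel_untouched(self, rng):
        vals = rng.binomial(2, 0.4, size=(40, 10)).astype(float)
        geno = _gm(vals)
        keep = (geno.minor_allele_freqs >= 0.2) & (geno.het_rates <= 0.6)
        geno = geno.subset_markers(keep)
        clean, rep = apply_marker_qc(geno, maf_min=0.2, het_max=0.6, r2_max=0.999)
        assert clean.marker_ids == geno.marker_ids
        assert rep.removed_maf == [] and rep.removed_het == []
        assert np.array_equal(clean.values, geno.values)

    def test_duplicate_columns_pruned_keep_first(self):
        col = np.array([0, 1, 2, 1, 0], dtype=float)
        vals = np.column_stack([col, col, np.array([2, 1, 0, 1, 2.0])])
        clean, rep = apply_marker_qc(_gm(vals), maf_min=0.01, het_max=1.0, r2_max=0.99)
        # brute-force r2: columns 0/1 identical (r2=1), column 2 is the exact
        # negative (r2 = 1 as well) -> only the first survives
        assert clean.marker_ids == ["M0"]
        assert set(rep.removed_ld) == {"M1", "M2"}

    def test_heterozygosity_filter(self):
        vals = np.tile([1.0, 1.0, 1.0, 0.0, 2.0], (4, 1)).T  # het rate 0.6 each col
        vals = np.column_stack([vals[:, 0], np.array([0, 0, 2, 2, 1.0])])
        clean, rep = apply_marker_qc(_gm(vals), maf_min=0.01, het_max=0.2, r2_max=1.0)
        assert "M0" in rep.removed_het
        assert clean.marker_ids == ["M1"]

    def test_all_missing_column_reported_separately(self):
        vals = np.array([[np.nan, 1.0], [np.nan, 2.0], [np.nan, 1.0]])
        clean, rep = apply_marker_qc(_gm(vals), maf_min=0.01, het_max=1.0, r2_max=1.0)
        assert rep.removed_all_missing == ["M0"]
        assert clean.marker_ids == ["M1"]

    def test_everything_removed_raises(self):
        vals = np.zeros((10, 2))
        vals[0, :] = 1.0  # MAF 0.05 > freq of 1/20
        with pytest.raises(EmptyPanelError):
            apply_marker_qc(_gm(vals), maf_min=0.2, het_max=1.0, r2_max=1.0)

    def test_qc_deterministic(self, rng):
        vals = rng.binomial(2, rng.uniform(0.05, 0.5, 50), size=(60, 50)).astype(float)
        g = _gm(vals)
        a, _ = apply_marker_qc(g, 0.05, 0.2, 0.99)
        b, _ = apply_marker_qc(g, 0.05, 0.2, 0.99)
        assert a.marker_ids == b.marker_ids


class TestStandardize:
    def test_hand_computed_column(self):
        g = _gm(np.array([[0.0], [1.0], [2.0], [1.0]]))
        W = standardize_markers(g)
        sd = np.sqrt(2.0 / 3.0)  # ddof=1 sd of (0,1,2,1)
        assert W.values[0, 0] == pytest.approx(-1.0 / sd)
        assert abs(W.values[:, 0].mean()) < 1e-10
        assert W.values[:, 0].std(ddof=1) == pytest.approx(1.0, abs=1e-10)

    def test_monomorphic_column_raises(self):
        g = _gm(np.ones((4, 1)))
        with pytest.raises(ValueError, match="monomorphic marker 'M0'"):
            standardize_markers(g)

    def test_columns_zero_mean_unit_sd(self, rng):
        vals = rng.binomial(2, rng.uniform(0.1, 0.5, 30), size=(50, 30)).astype(float)
        W = standardize_markers(_gm(vals))
        assert np.abs(W.values.mean(axis=0)).max() < 1e-10
        assert np.abs(W.values.std(axis=0, ddof=1) - 1).max() < 1e-10

    def test_missing_values_rejected(self):
        g = _gm([[0, np.nan], [1, 2], [2, 0]])
        with pytest.raises(ValueError, match="impute"):
            standardize_markers(g)

    def test_hwe_variant_centers_by_2p(self):
        g = _gm([[0.0], [1.0], [2.0], [1.0]])
        W = standardize_markers(g, use_allele_freqs=True)
        p = 0.5
        assert W.column_means[0] == pytest.approx(2 * p)
        assert W.column_sds[0] == pytest.approx(np.sqrt(2 * p * (1 - p)))
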