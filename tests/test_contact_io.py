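"""Contact-matrix container, cool round trips, expected profiles, thinning."""

import h5py
import numpy as np
import pytest

from contactdiff.contact_io import (
    ContactMatrix,
    compute_expected,
    downsample_counts,
    observed_over_expected,
    read_cool,
    read_coo_text,
    write_cool,
    write_coo_text,
)

from conftest import random_matrix


class TestContactMatrix:
    def test_rejects_lower_triangle_entries(self):
        with pytest.raises(ValueError, match="upper triangle"):
            ContactMatrix(chrom="c", resolution=5000, n_bins=4,
                          bin1=[2], bin2=[1], value=[1.0])

    def test_rejects_entries_on_missing_bins(self):
        with pytest.raises(ValueError, match="missing"):
            ContactMatrix(chrom="c", resolution=5000, n_bins=4,
                          bin1=[1], bin2=[2], value=[1.0],
                          missing=np.array([False, True, False, False]))

    def test_rejects_negative_and_nonfinite_values(self):
        for bad in (-1.0, np.nan, np.inf):
            with pytest.raises(ValueError):
                ContactMatrix(chrom="c", resolution=5000, n_bins=4,
                              bin1=[0], bin2=[1], value=[bad])

    def test_symmetric_query_and_zero_semantics(self):
        m = ContactMatrix(chrom="c", resolution=5000, n_bins=4,
                          bin1=[0], bin2=[2], value=[6.0],
                          missing=np.array([False, False, False, True]))
        assert m.get(0, 2) == m.get(2, 0) == 6.0
        assert m.get(0, 1) == 0.0          # absent pixel between valid bins
        assert np.isnan(m.get(0, 3))       # missing bin

    def test_dense_round_trip(self, rng):
        m = random_matrix(rng, n_bins=15, n_missing=3)
        back = ContactMatrix.from_dense(m.to_dense(np.nan), m.chrom,
                                        m.resolution, missing=m.missing)
        np.testing.assert_array_equal(back.bin1, m.bin1)
        np.testing.assert_allclose(back.value, m.value)


class TestCoolRoundTrip:
    def test_write_read_identity(self, tmp_path, rng):
        m = random_matrix(rng, n_bins=30, n_missing=4)
        path = str(tmp_path / "m.cool")
        write_cool(m, path)
        back = read_cool(path, m.chrom, m.resolution)
        np.testing.assert_array_equal(back.bin1, m.bin1)
        np.testing.assert_array_equal(back.bin2, m.bin2)
        np.testing.assert_allclose(back.value, m.value, rtol=1e-9)
        np.testing.assert_array_equal(back.missing, m.missing)

    def test_float_precision_preserved(self, tmp_path):
        m = ContactMatrix(chrom="c", resolution=5000, n_bins=3,
                          bin1=[0], bin2=[1], value=[0.0123456789])
        path = str(tmp_path / "m.cool")
        write_cool(m, path)
        back = read_cool(path, "c", 5000)
        assert abs(back.value[0] - 0.0123456789) / 0.0123456789 < 1e-9

    def test_balanced_values_match_hand_arithmetic(self, tmp_path):
        # 4-bin fixture: balanced = count * w_i * w_j
        counts = np.array([10, 4, 7])
        b1 = np.array([0, 0, 2])
        b2 = np.array([1, 2, 3])
        w = np.array([0.5, 0.2, 0.1, 0.4])
        m = ContactMatrix(chrom="c", resolution=5000, n_bins=4,
                          bin1=b1, bin2=b2,
                          value=counts * w[b1] * w[b2],
                          raw=counts, weights=w)
        path = str(tmp_path / "m.cool")
        write_cool(m, path)
        back = read_cool(path, "c", 5000)
        expected = [10 * 0.5 * 0.2, 4 * 0.5 * 0.1, 7 * 0.1 * 0.4]
        np.testing.assert_allclose(back.value, expected)

    def test_undefined_weight_bin_becomes_missing(self, tmp_path):
        w = np.array([1.0, np.nan, 1.0])
        m = ContactMatrix(chrom="c", resolution=5000, n_bins=3,
                          bin1=[0], bin2=[2], value=[5.0],
                          raw=np.array([5]), weights=w)
        path = str(tmp_path / "m.cool")
        write_cool(m, path)
        back = read_cool(path, "c", 5000)
        assert back.missing.tolist() == [False, True, False]
        assert all(back.bin1 != 1) and all(back.bin2 != 1)

    def test_disk_stores_upper_triangle_only(self, tmp_path, rng):
        m = random_matrix(rng, n_bins=12)
        path = str(tmp_path / "m.cool")
        write_cool(m, path)
        with h5py.File(path) as f:
            assert f["pixels/bin1_id"].shape[0] == m.n_entries
            assert np.all(f["pixels/bin1_id"][:] <= f["pixels/bin2_id"][:])

    def test_missing_chrom_and_wrong_resolution_fail(self, tmp_path, rng):
        m = random_matrix(rng, n_bins=5)
        path = str(tmp_path / "m.cool")
        write_cool(m, path)
        with pytest.raises(ValueError, match="not in file"):
            read_cool(path, "chrNope", 5000)
        with pytest.raises(ValueError, match="resolution"):
            read_cool(path, m.chrom, 1000)

    def test_coo_text_round_trip(self, tmp_path, rng):
        m = random_matrix(rng, n_bins=10, n_missing=2)
        path = str(tmp_path / "m.coo.tsv")
        write_coo_text(m, path)
        back = read_coo_text(path)
        np.testing.assert_allclose(back.value, m.value)
        np.testing.assert_array_equal(back.missing, m.missing)


class TestExpectedProfile:
    def test_constant_matrix_gives_constant_profile(self):
        n = 6
        iu, ju = np.triu_indices(n)
        m = ContactMatrix(chrom="c", resolution=5000, n_bins=n,
                          bin1=iu, bin2=ju, value=np.full(len(iu), 3.0))
        prof = compute_expected(m)
        np.testing.assert_allclose(prof.values, 3.0)

    def test_single_entry_profile(self):
        m = ContactMatrix(chrom="c", resolution=5000, n_bins=3,
                          bin1=[0], bin2=[2], value=[6.0])
        prof = compute_expected(m)
        assert prof.values[2] == 6.0       # one pixel at offset 2
        assert prof.values[1] == 0.0       # two absent pixels count as zero

    def test_matches_dense_brute_force_with_missing(self, rng):
        m = random_matrix(rng, n_bins=20, n_missing=3)
        prof = compute_expected(m)
        dense = m.to_dense(np.nan)
        for d in range(m.n_bins):
            diag = np.array([dense[i, i + d]
                             for i in range(m.n_bins - d)])
            diag = diag[~np.isnan(diag)]
            if len(diag):
                assert prof.values[d] == pytest.approx(diag.mean())
            else:
                assert np.isnan(prof.values[d])

    def test_all_missing_gives_empty_profile(self):
        m = ContactMatrix(chrom="c", resolution=5000, n_bins=3,
                          bin1=[], bin2=[], value=[],
                          missing=np.ones(3, dtype=bool))
        assert np.all(np.isnan(compute_expected(m).values) |
                      (compute_expected(m).values == 0) |
                      np.isnan(compute_expected(m).values))
        assert not np.any(np.nan_to_num(compute_expected(m).values) > 0)


class TestObservedOverExpected:
    def test_constant_matrix_gives_unit_oe(self):
        n = 5
        iu, ju = np.triu_indices(n)
        m = ContactMatrix(chrom="c", resolution=5000, n_bins=n,
                          bin1=iu, bin2=ju, value=np.full(len(iu), 2.0))
        oe = observed_over_expected(m, compute_expected(m))
        np.testing.assert_allclose(oe.value, 1.0)

    def test_matches_elementwise_brute_force(self, rng):
        m = random_matrix(rng, n_bins=25, n_missing=2)
        prof = compute_expected(m)
        oe = observed_over_expected(m, prof)
        for i, j, v in zip(oe.bin1, oe.bin2, oe.value):
            assert v == pytest.approx(m.get(i, j) / prof.values[j - i])

    def test_mismatched_profile_rejected(self, rng):
        m = random_matrix(rng, n_bins=10)
        prof = compute_expected(m)
        prof.chrom = "other"
        with pytest.raises(ValueError):
            observed_over_expected(m, prof)


class TestDownsampleCounts:
    def test_fraction_one_is_identity(self, rng):
        m = random_matrix(rng, n_bins=10, with_raw=True)
        out = downsample_counts(m, 1.0, seed=0)
        np.testing.assert_array_equal(out.raw, m.raw)

    def test_total_within_binomial_bounds(self):
        # total count 1e6 thinned at 1/4: expect 2.5e5 +/- 4 sd
        n_entries = 1000
        counts = np.full(n_entries, 1000)
        iu, ju = np.triu_indices(100)
        sel = slice(0, n_entries)
        m = ContactMatrix(chrom="c", resolution=5000, n_bins=100,
                          bin1=iu[sel], bin2=ju[sel],
                          value=counts * 1e-4, raw=counts,
                          weights=np.full(100, 0.01))
        out = downsample_counts(m, 0.25, seed=1)
        total = out.raw.sum()
        sd = np.sqrt(1e6 * 0.25 * 0.75)
        assert abs(total - 2.5e5) < 4 * sd

    def test_deterministic_and_bounded(self, rng):
        m = random_matrix(rng, n_bins=15, with_raw=True)
        a = downsample_counts(m, 0.3, seed=9)
        b = downsample_counts(m, 0.3, seed=9)
        np.testing.assert_array_equal(a.raw, b.raw)
        # never exceeds original; zeros stay zero (dropped entries)
        orig = {(i, j): c for i, j, c in zip(m.bin1, m.bin2, m.raw)}
        for i, j, c in zip(a.bin1, a.bin2, a.raw):
            assert c <= orig[(i, j)]

    def test_invalid_fraction_rejected(self, rng):
        m = random_matrix(rng, n_bins=5, with_raw=True)
        for frac in (0.0, 1.5, -0.1):
            with pytest.raises(ValueError):
                downsample_counts(m, frac, seed=0)
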