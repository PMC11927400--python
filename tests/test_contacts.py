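import numpy as np
import pytest
import scipy.sparse as sp

import genedomains as gd
from genedomains.contacts import n_bins_for
from helpers import dense_to_matrix, uniform_matrix


def write_lines(path, lines):
    path.write_text("\n".join(lines) + "\n")
    return str(path)


class TestTripletReader:
    def test_empty_file_gives_empty_matrix(self, tmp_path):
        p = write_lines(tmp_path / "c.txt", ["# empty"])
        m = gd.read_contacts(p, "triplet", "chr1", 250, chrom_length=10_000)
        assert m.n_bins == 40
        assert m.counts.nnz == 0

    def test_transposition_and_duplicate_merge(self, tmp_path):
        p = write_lines(
            tmp_path / "c.txt", ["0\t500\t4", "500\t0\t2", "250\t250\t7"]
        )
        m = gd.read_contacts(p, "triplet", "chr1", 250, chrom_length=1000)
        assert m.counts[0, 2] == 6
        assert m.counts[1, 1] == 7
        assert m.counts.nnz == 2

    def test_ceil_bin_count(self):
        assert n_bins_for(2_000_000, 250) == 8000
        assert n_bins_for(1001, 250) == 5

    def test_malformed_line_reports_line_number(self, tmp_path):
        p = write_lines(tmp_path / "c.txt", ["0\t0\t1", "0\tx\t2"])
        with pytest.raises(ValueError, match=":2"):
            gd.read_contacts(p, "triplet", "chr1", 250, chrom_length=1000)

    def test_round_trip_exact(self, tmp_path, small_sim):
        _, _, _, m, _ = small_sim
        path = tmp_path / "rt.txt"
        gd.write_triplet(m, str(path))
        back = gd.read_contacts(
            str(path), "triplet", m.chrom, m.resolution, chrom_length=m.chrom_length
        )
        assert (back.counts != m.counts).nnz == 0


class TestCoolReader:
    @staticmethod
    def _write_cool(path, n, pixels, weights=None):
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("chroms/name", data=[b"chr1", b"chr2"])
            f.create_dataset("chroms/length", data=[n * 250, 1000])
            chrom = [0] * n + [1] * 4
            start = [i * 250 for i in range(n)] + [0, 250, 500, 750]
            f.create_dataset("bins/chrom", data=chrom)
            f.create_dataset("bins/start", data=start)
            f.create_dataset("bins/end", data=[s + 250 for s in start])
            if weights is not None:
                f.create_dataset("bins/weight", data=list(weights) + [1.0] * 4)
            b1, b2, c = zip(*pixels)
            f.create_dataset("pixels/bin1_id", data=b1)
            f.create_dataset("pixels/bin2_id", data=b2)
            f.create_dataset("pixels/count", data=c)

    def test_reads_requested_chromosome(self, tmp_path):
        path = str(tmp_path / "t.cool")
        self._write_cool(path, 4, [(0, 1, 5), (1, 3, 2)])
        m = gd.read_contacts(path, "cool", "chr1", 250)
        assert m.n_bins == 4
        assert m.counts[0, 1] == 5 and m.counts[1, 3] == 2
        assert m.normalization == "raw"

    def test_weights_applied_as_external_normalization(self, tmp_path):
        path = str(tmp_path / "t.cool")
        self._write_cool(path, 4, [(0, 1, 8)], weights=[0.5, 0.5, 1, 1])
        m = gd.read_contacts(path, "cool", "chr1", 250)
        assert m.normalization == "external"
        assert m.counts[0, 1] == pytest.approx(2.0)

    def test_unknown_chromosome_names_available(self, tmp_path):
        path = str(tmp_path / "t.cool")
        self._write_cool(path, 4, [(0, 1, 5)])
        with pytest.raises(ValueError, match="chr1"):
            gd.read_contacts(path, "cool", "chrX", 250)


def test_hic_backend_absent_degrades_clearly(tmp_path):
    p = tmp_path / "x.hic"
    p.write_bytes(b"")
    with pytest.raises((RuntimeError, ImportError), match="hic"):
        gd.read_contacts(str(p), "hic", "chr1", 250, chrom_length=1000)


class TestBalancing:
    def test_symmetric_input_unchanged_up_to_scale(self):
        arr = np.full((5, 5), 2.0)
        m = dense_to_matrix(arr, normalization="raw")
        b = gd.balance_matrix(m)
        d = b.dense()
        assert np.allclose(d, d[0, 0] * arr / arr[0, 0])

    def test_matches_bruteforce_fixed_point(self):
        arr = np.array([[4.0, 2.0, 1.0], [2.0, 6.0, 3.0], [1.0, 3.0, 5.0]])
        m = dense_to_matrix(arr, normalization="raw")
        out = gd.balance_matrix(m, max_iter=10_000, tol=1e-12).dense()
        # independent dense alternating-scaling oracle
        x = arr.copy()
        for _ in range(100_000):
            marg = x.sum(axis=1)
            step = marg / marg.mean()
            if np.max(np.abs(step - 1)) < 1e-14:
                break
            x /= np.outer(step, step)
        assert np.allclose(out / out.sum(), x / x.sum(), atol=1e-10)

    def test_zero_row_masked_and_dropped(self):
        arr = np.array([[4.0, 2.0, 0.0], [2.0, 6.0, 0.0], [0.0, 0.0, 0.0]])
        m = dense_to_matrix(arr, normalization="raw")
        b = gd.balance_matrix(m)
        assert b.mask.tolist() == [False, False, True]
        assert b.counts[:, 2].nnz == 0 and b.counts[2, :].nnz == 0

    def test_idempotence(self, small_sim):
        _, _, _, m, _ = small_sim
        again = gd.ContactMatrix(
            m.chrom, m.chrom_length, m.resolution, m.counts.copy(),
            normalization="raw", mask=m.mask.copy(),
        )
        b2 = gd.balance_matrix(again, tol=1e-8)
        a = m.counts.toarray()
        c = b2.counts.toarray()
        scale = c.sum() / a.sum()
        assert np.allclose(c, a * scale, rtol=1e-4)


class TestExpectedProfile:
    def test_uniform_matrix_flat_profile(self):
        m = uniform_matrix(6, value=3.0)
        e = gd.expected_profile(m)
        assert np.allclose(e.expected, 3.0)

    def test_hand_computed_means_with_zero_pairs(self):
        # 4 bins; stored: (0,1)=2, (1,2)=4, (0,2)=3; (2,3) and (1,3) unstored
        arr = np.zeros((4, 4))
        arr[0, 1] = arr[1, 0] = 2
        arr[1, 2] = arr[2, 1] = 4
        arr[0, 2] = arr[2, 0] = 3
        e = gd.expected_profile(dense_to_matrix(arr))
        assert e.expected[1] == pytest.approx((2 + 4 + 0) / 3)
        assert e.expected[2] == pytest.approx((3 + 0) / 2)

    def test_masked_bin_excluded_from_means(self):
        arr = np.ones((5, 5))
        m = dense_to_matrix(arr)
        m.mask[2] = True
        m.counts = sp.csr_matrix(np.triu(arr * np.outer(~m.mask, ~m.mask)))
        e = gd.expected_profile(m)
        # separation 1 valid pairs: (0,1),(3,4) -> both stored as 1
        assert e.expected[1] == pytest.approx(1.0)

    def test_oe_mean_is_one_per_separation(self, small_sim):
        _, _, _, m, e = small_sim
        n = m.n_bins
        coo = m.counts.tocoo()
        for d in (1, 5, 20):
            sums = coo.data[(coo.col - coo.row) == d].sum()
            assert sums / ((n - d) * e.expected[d]) == pytest.approx(1.0, abs=1e-9)


class TestOEValues:
    def test_uniform_gives_unit_oe(self):
        m = uniform_matrix(8)
        e = gd.expected_profile(m)
        region = np.array([[0, 3], [1, 4], [2, 5]])
        assert np.allclose(gd.oe_values(m, e, region), 1.0)

    def test_division_by_expected(self):
        arr = np.zeros((10, 10))
        arr[3, 7] = arr[7, 3] = 6.0
        m = dense_to_matrix(arr)
        e = gd.ExpectedProfile(250, np.full(10, 2.0))
        assert gd.oe_values(m, e, np.array([[3, 7]]))[0] == pytest.approx(3.0)

    def test_masked_pairs_dropped(self):
        m = uniform_matrix(10)
        m.mask[4] = True
        e = gd.ExpectedProfile(250, np.ones(10))
        region = np.array([[0, 4], [1, 4], [2, 5], [3, 6], [2, 7]])
        assert gd.oe_values(m, e, region).size == 3
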