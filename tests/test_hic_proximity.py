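"""Tests for contact-matrix handling, ICE balancing, insulation-score CID
calling, and the recombination-weight models."""

import numpy as np
import pytest

from sgc import (
    ContactMatrix,
    deletion_cid_concordance,
    ice_balance,
    insulation_cids,
    make_synthetic_hic,
    read_triplet,
    weights_for_sites,
    write_triplet,
)
from sgc.hic_proximity import insulation_score
from sgc.lu_profiler import LuProfile


class TestTripletIO:
    def test_small_file_is_symmetrized(self, tmp_path):
        p = tmp_path / "m.txt"
        p.write_text("0\t1\t5\n2\t2\t3\n")
        m = read_triplet(p, 2000, n_bins=3)
        assert m.counts[0, 1] == m.counts[1, 0] == 5
        assert m.counts[2, 2] == 3

    def test_round_trip(self, tmp_path):
        m = make_synthetic_hic(25, 2000, [8, 16], noise=0.1, seed=5)
        write_triplet(m, tmp_path / "m.txt")
        again = read_triplet(tmp_path / "m.txt", 2000, n_bins=25)
        assert np.allclose(m.counts, again.counts, rtol=1e-5)

    def test_empty_file_gives_zero_matrix(self, tmp_path):
        p = tmp_path / "e.txt"
        p.write_text("")
        m = read_triplet(p, 2000, n_bins=4)
        assert m.counts.shape == (4, 4) and not m.counts.any()

    def test_negative_and_out_of_range_rejected(self, tmp_path):
        p = tmp_path / "bad.txt"
        p.write_text("0\t1\t-2\n")
        with pytest.raises(ValueError, match="negative"):
            read_triplet(p, 2000, n_bins=3)
        p.write_text("0\t9\t1\n")
        with pytest.raises(ValueError, match="range"):
            read_triplet(p, 2000, n_bins=3)


class TestIceBalance:
    def test_uniform_matrix_unchanged_up_to_scale(self):
        m = ContactMatrix(np.ones((6, 6)), 2000)
        b = ice_balance(m, filter_low_pct=0)
        ratio = b.counts / m.counts
        assert np.allclose(ratio, ratio[0, 0])

    def test_rank_one_matrix_balances_to_constant(self):
        """For counts = v v^T, iterative sqrt-correction converges to a
        constant matrix (closed form: dividing by sqrt(row sums) removes v
        exactly)."""
        v = np.array([1.0, 2.0])
        m = ContactMatrix(np.outer(v, v), 2000)
        b = ice_balance(m, filter_low_pct=0, tol=1e-8)
        sums = b.counts.sum(axis=1)
        assert abs(sums[0] - sums[1]) < 1e-6
        assert np.allclose(b.counts, b.counts[0, 0])

    def test_row_sums_equalized_on_structured_matrix(self):
        m = make_synthetic_hic(30, 2000, [10, 20], noise=0.2, seed=1)
        b = ice_balance(m, tol=1e-6)
        live = [i for i in range(30) if i not in b.masked_bins]
        sums = b.counts[np.ix_(live, live)].sum(axis=1)
        assert sums.std() / sums.mean() < 1e-5

    def test_zero_coverage_bin_is_masked(self):
        c = np.ones((5, 5))
        c[2, :] = 0
        c[:, 2] = 0
        b = ice_balance(ContactMatrix(c, 2000), filter_low_pct=0)
        assert 2 in b.masked_bins

    def test_idempotence(self):
        m = make_synthetic_hic(40, 2000, [12, 25], noise=0.1, seed=2)
        b1 = ice_balance(m, tol=1e-7)
        b2 = ice_balance(b1, filter_low_pct=0, tol=1e-7)
        live = [i for i in range(40) if i not in b1.masked_bins]
        s1 = b1.counts[np.ix_(live, live)].sum(axis=1)
        s2 = b2.counts[np.ix_(live, live)].sum(axis=1)
        assert np.allclose(s1 / s1.mean(), s2 / s2.mean(), atol=1e-5)

    def test_all_masked_rejected(self):
        with pytest.raises(ValueError, match="masked"):
            ice_balance(ContactMatrix(np.zeros((3, 3)), 2000))


class TestInsulationCids:
    def test_constant_matrix_has_no_boundaries(self):
        m = ContactMatrix(np.ones((30, 30)), 2000)
        assert insulation_cids(m).boundaries == ()

    def test_noise_free_planted_boundary_recovered_exactly(self):
        m = make_synthetic_hic(50, 2000, [17, 33], noise=0.0)
        seg = insulation_cids(ice_balance(m, filter_low_pct=0))
        assert seg.boundaries == (17, 33)
        assert seg.domains == ((0, 17), (17, 33), (33, 50))

    def test_three_boundaries_with_noise_at_one_bin_tolerance(self):
        planted = [10, 18, 30]
        m = make_synthetic_hic(40, 2000, planted, noise=0.05, seed=11)
        seg = insulation_cids(ice_balance(m))
        assert len(seg.boundaries) == 3  # precision == recall == 1
        assert all(min(abs(b - p) for p in planted) <= 1
                   for b in seg.boundaries)

    def test_scaling_invariance(self):
        m = make_synthetic_hic(40, 2000, [15, 28], noise=0.1, seed=3)
        s1 = insulation_score(m)
        s2 = insulation_score(ContactMatrix(m.counts * 37.5, 2000))
        assert np.allclose(s1, s2, equal_nan=True)

    def test_oversized_window_rejected(self):
        m = ContactMatrix(np.ones((6, 6)), 2000)
        with pytest.raises(ValueError, match="window"):
            insulation_cids(m, window_bins=4)


class TestWeightModels:
    def test_power_law_ratio_is_exact(self):
        w = weights_for_sites([0.0, 1000.0, 10_000.0], "power_law",
                              {"alpha": 1.0, "d0": 1e-9}).matrix
        assert w[0, 1] / w[0, 2] == pytest.approx(10.0)

    def test_cid_boost_multiplies_same_domain_pairs(self):
        m = make_synthetic_hic(30, 2000, [15], noise=0.0)
        cids = insulation_cids(ice_balance(m, filter_low_pct=0))
        pos = [1000, 9000, 41_000]  # two in domain 0 (< bin 15), one beyond
        w5 = weights_for_sites(pos, "cid_boost", {"alpha": 1.0, "d0": 1.0,
                                                  "beta": 5.0},
                               cids=cids).matrix
        w1 = weights_for_sites(pos, "power_law",
                               {"alpha": 1.0, "d0": 1.0}).matrix
        assert w5[0, 1] / w1[0, 1] == pytest.approx(5.0)
        assert w5[0, 2] / w1[0, 2] == pytest.approx(1.0)

    def test_hic_contact_reads_reference_bins(self):
        m = make_synthetic_hic(20, 2000, [], alpha=1.0, noise=0.0)
        w = weights_for_sites([0, 4000, 12_000], "hic_contact",
                              matrix=m).matrix
        assert w[0, 1] == pytest.approx(m.counts[0, 2])
        assert w[0, 2] == pytest.approx(m.counts[0, 6])
        assert np.diagonal(w).sum() == 0

    def test_missing_inputs_rejected(self):
        with pytest.raises(ValueError, match="matrix"):
            weights_for_sites([0, 1000], "hic_contact")
        with pytest.raises(ValueError, match="CID"):
            weights_for_sites([0, 1000], "cid_boost")

    def test_weights_symmetric_zero_diagonal(self):
        w = weights_for_sites([0, 5000, 9000, 20_000], "power_law").matrix
        assert np.allclose(w, w.T) and not np.diagonal(w).any()


class TestConcordance:
    def _profile(self, segments):
        return LuProfile("x", {}, tuple(segments))

    def test_segments_inside_one_domain_score_one(self):
        m = make_synthetic_hic(30, 2000, [15], noise=0.0)
        cids = insulation_cids(ice_balance(m, filter_low_pct=0))
        p = self._profile([(2000, 10_000), (34_000, 40_000)])
        assert deletion_cid_concordance([p], cids) == 1.0

    def test_boundary_straddling_segment_is_discordant(self):
        m = make_synthetic_hic(30, 2000, [15], noise=0.0)
        cids = insulation_cids(ice_balance(m, filter_low_pct=0))
        p = self._profile([(20_000, 40_000)])
        assert deletion_cid_concordance([p], cids) == 0.0

    def test_no_segments_is_nan(self):
        m = make_synthetic_hic(30, 2000, [15], noise=0.0)
        cids = insulation_cids(ice_balance(m, filter_low_pct=0))
        assert np.isnan(deletion_cid_concordance([self._profile([])], cids))
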