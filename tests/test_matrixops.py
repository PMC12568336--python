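"""Binning arithmetic, ICE balancing, coverage, decay, aggregation, correlation."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

import loopscape as ls
from loopscape.genome import ConfigError
from loopscape.matrixops import ContactMatrix
from .conftest import matrices_for, qc_chain

GENOME1 = ls.GenomeSpec(("chr1",), {"chr1": 1_000_000})


def _cis_matrix(dense: np.ndarray, resolution=10_000) -> ContactMatrix:
    up = np.triu(dense)
    return ContactMatrix(resolution, "chr1", "chr1", sp.csr_matrix(up))


def _valid_frame(rows):
    df = pd.DataFrame(rows, columns=["chrom1", "pos1", "chrom2", "pos2"])
    df["valid"] = True
    return df


class TestBinPairs:
    def test_bin_arithmetic(self):
        ms = ls.bin_pairs(_valid_frame([("chr1", 1, "chr1", 10_001)]), GENOME1, 10_000)
        assert ms.cis["chr1"].counts[0, 1] == 1

    def test_repeated_bin_pair_accumulates(self):
        rows = [("chr1", 1, "chr1", 10_001), ("chr1", 5, "chr1", 10_005)]
        ms = ls.bin_pairs(_valid_frame(rows), GENOME1, 10_000)
        assert ms.cis["chr1"].counts[0, 1] == 2

    def test_mass_conservation(self, qc_fixture):
        pairs, _, genome = qc_fixture
        classified, _ = qc_chain(pairs, genome, chimeric_filter=False)
        ms = ls.bin_pairs(classified, genome, 10_000)
        assert ms.total_mass() == ms.n_pairs == int(classified["valid"].sum())

    def test_nonpositive_resolution_rejected(self):
        with pytest.raises(ConfigError):
            ls.bin_pairs(_valid_frame([("chr1", 1, "chr1", 2)]), GENOME1, 0)


class TestBalance:
    def test_uniform_matrix_gets_equal_weights(self):
        bm = ls.balance(_cis_matrix(np.ones((30, 30))))
        w = bm.weights[~bm.mask]
        assert np.allclose(w, w[0])
        assert bm.balance_converged

    def test_marginals_uniform_within_tolerance(self, comp_fixture):
        bm, _ = comp_fixture
        bal = bm.balanced_dense()
        marg = bal.sum(axis=1)[~bm.mask]
        assert np.abs(marg / marg.mean() - 1).max() < 1e-4

    def test_idempotent_on_balanced_fixture(self, comp_fixture):
        bm, _ = comp_fixture
        again = ls.balance(bm)
        a, b = again.weights, bm.weights
        both = np.isfinite(a) & np.isfinite(b)
        assert np.allclose(a[both], b[both], rtol=1e-3)

    def test_zero_row_masked_with_undefined_weight(self):
        d = np.ones((20, 20))
        d[5, :] = 0
        d[:, 5] = 0
        bm = ls.balance(_cis_matrix(d))
        assert bm.mask[5]
        assert np.isnan(bm.weights[5])


class TestCoverage:
    def test_cis_only_fixture_has_unit_ratio(self):
        g = ls.generate_genome(1, (5_000_000, 5_000_000), 1)
        params = ls.SimParams(n_pairs=20_000, trans_fraction=0.0, duplicate_rate=0.0,
                              unmapped_rate=0.0, short_fraction=0.0, seed=3)
        ms, _ = matrices_for(params, g)
        cov = ls.coverage(ms)
        r = cov.ratio["chr1"]
        assert np.allclose(r[np.isfinite(r)], 1.0)
        assert cov.mean_ratio == pytest.approx(1.0)

    def test_trans_fraction_04_gives_mean_ratio_06(self):
        g = ls.generate_genome(2, (10_000_000, 10_000_000), 6)
        params = ls.SimParams(n_pairs=100_000, trans_fraction=0.4, duplicate_rate=0.0,
                              unmapped_rate=0.0, short_fraction=0.0, seed=8)
        ms, _ = matrices_for(params, g)
        cov = ls.coverage(ms)
        se = 3 * np.sqrt(0.4 * 0.6 / params.n_pairs)
        assert abs(cov.mean_ratio - 0.6) < max(3 * se, 0.02)

    def test_empty_bins_excluded_from_mean(self):
        rows = [("chr1", 1, "chr1", 500_001)]
        ms = ls.bin_pairs(_valid_frame(rows), GENOME1, 10_000)
        cov = ls.coverage(ms)
        assert np.isnan(cov.ratio["chr1"][5])
        assert cov.mean_ratio == pytest.approx(1.0)


class TestContactDecay:
    def test_slope_recovery_across_alphas(self, alpha_decay_slopes):
        for alpha, slope in alpha_decay_slopes.items():
            assert abs(slope - (-alpha)) < 0.1, alpha

    def test_chromosomes_share_decay_profile(self):
        g = ls.generate_genome(2, (20_000_000, 20_000_000), 9)
        params = ls.SimParams(n_pairs=400_000, trans_fraction=0.0, duplicate_rate=0.0,
                              unmapped_rate=0.0, short_fraction=0.0, seed=10)
        ms, _ = matrices_for(params, g)
        curves = ls.contact_decay(ms)
        s1 = curves["chr1"].slope()
        s2 = curves["chr2"].slope()
        assert abs(s1 - s2) < 0.1

    def test_single_distance_yields_single_nonzero_bin(self):
        ms = ls.bin_pairs(_valid_frame([("chr1", 1, "chr1", 100_001)] * 5), GENOME1, 10_000)
        curve = ls.contact_decay(ms)["chr1"]
        assert (curve.prob > 0).sum() == 1

    def test_unit_mass_normalization(self, loop_fixture):
        _, raw, _ = loop_fixture
        ms = ls.MatrixSet(raw.resolution, ls.generate_genome(1, (30_000_000, 30_000_000), 4),
                          {"chr1": raw}, {}, int(raw.counts.sum()))
        curve = ls.contact_decay(ms)["all"]
        assert float((curve.prob * curve.npairs).sum()) == pytest.approx(1.0, rel=1e-6)


class TestFixedBinView:
    def test_shape_and_mass_conservation(self, qc_fixture):
        pairs, _, genome = qc_fixture
        classified, _ = qc_chain(pairs, genome, chimeric_filter=False)
        ms = ls.bin_pairs(classified, genome, 10_000)
        view, labels = ls.fixed_bin_view(ms, n_bins=100)
        assert view.shape == (200, 200)
        assert len(labels) == 200
        assert view.sum() == pytest.approx(ms.total_mass())

    def test_one_to_one_when_native_equals_coarse(self):
        # 1 Mb at 10 kb = exactly 100 native bins: aggregation is the identity
        ms = ls.bin_pairs(_valid_frame([("chr1", 1, "chr1", 990_001)]), GENOME1, 10_000)
        view, _ = ls.fixed_bin_view(ms, n_bins=100)
        assert view[0, 99] == 1


class TestCorrelateReplicates:
    def test_self_correlation_is_one(self, qc_fixture):
        pairs, _, genome = qc_fixture
        classified, _ = qc_chain(pairs, genome, chimeric_filter=False)
        ms = ls.bin_pairs(classified, genome, 10_000)
        assert ls.correlate_replicates(ms, ms) == pytest.approx(1.0)

    def test_permuted_copy_decorrelates(self):
        g = ls.generate_genome(1, (10_000_000, 10_000_000), 5)
        params = ls.SimParams(n_pairs=100_000, trans_fraction=0.0, duplicate_rate=0.0,
                              unmapped_rate=0.0, short_fraction=0.0, seed=6)
        ms, _ = matrices_for(params, g)
        rng = np.random.default_rng(0)
        dense = ms.cis["chr1"].dense()
        perm = rng.permutation(dense.shape[0])
        shuffled = np.triu(dense[np.ix_(perm, perm)])
        ms_perm = ls.MatrixSet(ms.resolution, g, {"chr1": ContactMatrix(
            ms.resolution, "chr1", "chr1", sp.csr_matrix(shuffled))}, {}, ms.n_pairs)
        r_self = ls.correlate_replicates(ms, ms)
        r_perm = ls.correlate_replicates(ms, ms_perm)
        assert abs(r_perm) < 0.3
        assert r_self > 0.9

    def test_independent_replicates_below_identical(self):
        g = ls.generate_genome(1, (10_000_000, 10_000_000), 5)
        mss = []
        for seed in (6, 7):
            params = ls.SimParams(n_pairs=100_000, trans_fraction=0.0, duplicate_rate=0.0,
                                  unmapped_rate=0.0, short_fraction=0.0, seed=seed)
            mss.append(matrices_for(params, g)[0])
        r_rep = ls.correlate_replicates(mss[0], mss[1])
        assert 0 < r_rep < ls.correlate_replicates(mss[0], mss[0])

    def test_disjoint_support_is_undefined(self):
        a = ls.bin_pairs(_valid_frame([("chr1", 1, "chr1", 100_001)]), GENOME1, 10_000)
        b = ls.bin_pairs(_valid_frame([("chr1", 1, "chr1", 200_001)]), GENOME1, 10_000)
        assert np.isnan(ls.correlate_replicates(a, b))
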