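"""Expected-model fitting, binomial tails, FDR, locus queries, trans ranking."""

from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest

import loopscape as ls
from loopscape.significance import fit_expected, query_locus, rank_trans
from loopscape.significance import test_interactions as score_interactions
from .conftest import matrices_for


def exact_binom_upper_tail(k: int, n: int, p: Fraction) -> float:
    """Exact-rational enumeration of P(X >= k), X ~ Binomial(n, p)."""
    total = Fraction(0)
    for j in range(k, n + 1):
        total += comb(n, j) * p**j * (1 - p) ** (n - j)
    return float(total)


def brute_force_bh(p: np.ndarray) -> np.ndarray:
    """Textbook Benjamini-Hochberg: q_i = min_{j: p_j >= p_i} (m * p_j / rank_j)."""
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    prev = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        prev = min(prev, m * p[i] / rank_from_top)
        q[i] = prev
    return q


class TestBinomialTail:
    def test_matches_exact_enumeration_up_to_n_30(self):
        from scipy.stats import binom

        for n in (1, 2, 5, 10, 20, 30):
            for p in (Fraction(1, 100), Fraction(1, 10), Fraction(1, 2), Fraction(9, 10)):
                for k in range(0, n + 1):
                    ours = float(binom.sf(k - 1, n, float(p)))
                    exact = exact_binom_upper_tail(k, n, p)
                    assert ours == pytest.approx(exact, abs=1e-12), (n, p, k)

    def test_small_case_from_first_principles(self):
        # N=20 trials at p=0.1, observed 5: exact enumeration to 1e-12
        from scipy.stats import binom

        exact = exact_binom_upper_tail(5, 20, Fraction(1, 10))
        assert float(binom.sf(4, 20, 0.1)) == pytest.approx(exact, abs=1e-12)


class TestBH:
    @pytest.mark.parametrize("size", [1, 10, 137, 1000])
    def test_matches_brute_force_on_random_vectors(self, size):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(size)
        p = rng.random(size) ** 2
        ours = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(ours, brute_force_bh(p), atol=1e-12)


class TestFitExpected:
    def test_probabilities_non_increasing(self, loop_fixture):
        _, raw, _ = loop_fixture
        model = fit_expected(raw)
        assert (np.diff(model.probs) <= 1e-15).all()
        assert (model.probs >= 0).all()

    def test_occupancies_within_one(self, loop_fixture):
        _, raw, _ = loop_fixture
        model = fit_expected(raw)
        occ = model.pairs_per_stratum
        assert occ.max() - occ.min() <= 1

    def test_expected_sums_to_unit_probability(self, loop_fixture):
        _, raw, _ = loop_fixture
        model = fit_expected(raw)
        n = raw.n_bins
        d = np.arange(1, n)
        total = float((model.prob_at(d) * (n - d)).sum())
        assert total == pytest.approx(1.0, rel=1e-9)

    def test_single_stratum_equals_global_mean(self, loop_fixture):
        _, raw, _ = loop_fixture
        model = fit_expected(raw, n_strata=1)
        n = raw.n_bins
        total_pairs = n * (n - 1) // 2
        expect = 1.0 / total_pairs
        assert model.probs[0] == pytest.approx(expect, rel=1e-9)

    def test_few_pairs_reduce_strata_with_warning(self):
        import scipy.sparse as sp
        from loopscape.matrixops import ContactMatrix

        cm = ContactMatrix(10_000, "chr1", "chr1", sp.csr_matrix(np.triu(np.ones((5, 5)), 1)))
        with pytest.warns(UserWarning, match="reducing strata"):
            model = fit_expected(cm, n_strata=100)
        assert len(model.probs) <= 10


class TestTestInteractions:
    def test_oe_is_observed_over_expected(self, loop_fixture):
        _, raw, _ = loop_fixture
        model = fit_expected(raw)
        table = score_interactions(raw, model)
        finite = np.isfinite(table["oe"])
        assert np.allclose(table.loc[finite, "oe"], table.loc[finite, "observed"] / table.loc[finite, "expected"])
        assert (table["q"] >= table["p"] - 1e-12).all()

    def test_planted_loops_significant_at_q_005(self, loop_fixture):
        _, raw, truth = loop_fixture
        model = fit_expected(raw)
        table = score_interactions(raw, model)
        for b1, b2, _ in truth.loop_bins("chr1"):
            row = table[(table["bin1"] == b1) & (table["bin2"] == b2)]
            assert len(row) == 1
            assert row["q"].iloc[0] < 0.05

    def test_false_positive_rate_on_loop_free_fixture(self, null_fixture):
        _, raw = null_fixture
        model = fit_expected(raw)
        table = score_interactions(raw, model)
        fpr = (table["q"] < 0.05).mean()
        assert fpr <= 0.075

    def test_midpoints_at_bin_centers(self, loop_fixture):
        _, raw, _ = loop_fixture
        model = fit_expected(raw)
        table = score_interactions(raw, model).head(100)
        assert ((table["mid1"] % raw.resolution) == raw.resolution // 2).all()


class TestQueryLocus:
    def test_query_at_planted_loop_finds_it(self, loop_fixture):
        _, raw, truth = loop_fixture
        model = fit_expected(raw)
        table = score_interactions(raw, model)
        b1, b2, _ = truth.loop_bins("chr1")[0]
        res = raw.resolution
        q = query_locus(table, ("chr1", b1 * res, (b1 + 1) * res), ("chr1", b2 * res, (b2 + 1) * res), res)
        assert q.found
        assert ((q.hits["bin1"] == b1) & (q.hits["bin2"] == b2)).any()

    def test_contact_free_desert_not_found(self, loop_fixture):
        _, raw, _ = loop_fixture
        model = fit_expected(raw)
        table = score_interactions(raw, model)
        # an interval pair beyond the chromosome end can hold no contacts
        far = raw.n_bins * raw.resolution
        q = query_locus(table, ("chr1", far + 10**7, far + 10**7 + 10_000),
                        ("chr1", far + 2 * 10**7, far + 2 * 10**7 + 10_000), raw.resolution)
        assert not q.found
        assert q.hits.empty

    def test_multiple_hits_flagged_ambiguous(self, loop_fixture):
        _, raw, _ = loop_fixture
        model = fit_expected(raw)
        table = score_interactions(raw, model)
        res = raw.resolution
        q = query_locus(table, ("chr1", 0, 50 * res), ("chr1", 0, 50 * res), res)
        if len(q.hits) > 1:
            assert q.ambiguous


@pytest.fixture(scope="module")
def trans_set():
    g = ls.generate_genome(3, (10_000_000, 10_000_000), 14)
    params = ls.SimParams(n_pairs=150_000, trans_fraction=0.5, duplicate_rate=0.0,
                          unmapped_rate=0.0, short_fraction=0.0, seed=15)
    ms, _ = matrices_for(params, g)
    return ms


class TestRankTrans:

    def test_k_equal_one_returns_single_maximum(self, trans_set):
        top, _ = rank_trans(trans_set, k=1)
        assert len(top) == 1
        all_counts = [float(cm.counts.max()) for cm in trans_set.trans.values()]
        assert top["count"].iloc[0] == max(all_counts)

    def test_list_never_longer_than_k(self, trans_set):
        top, _ = rank_trans(trans_set, k=100)
        assert len(top) <= 100
        assert (top["count"].diff().dropna() <= 0).all()

    def test_uniform_trans_gives_similar_pair_means(self, trans_set):
        _, intensity = rank_trans(trans_set, k=10)
        vals = intensity.values[np.triu_indices(3, 1)]
        assert vals.std() / vals.mean() < 0.2

    def test_requesting_more_than_available_warns(self, trans_set):
        n_nonzero = sum(cm.counts.nnz for cm in trans_set.trans.values())
        with pytest.warns(UserWarning, match="available"):
            top, _ = rank_trans(trans_set, k=n_nonzero + 10**6)
        assert len(top) == n_nonzero
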