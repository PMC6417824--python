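"""Wilcoxon rank-sum testing, BH adjustment, and the k-mer screens."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats as sps

from mi2p import (
    bh_qvalues,
    build_matrix,
    identify_abundant_kmers,
    select_differential_kmers,
    wrs_test,
)
from mi2p.differential import TIED, UP_IN_GROUP1, UP_IN_GROUP2
from mi2p.kmers import KmerCountMatrix


def brute_force_wrs(x, y):
    """Exact two-sided p by enumerating every assignment of ranks to group 1."""
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    n1 = len(x)
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    us = []
    for combo in itertools.combinations(range(len(pooled)), n1):
        u = ranks[list(combo)].sum() - n1 * (n1 + 1) / 2
        us.append(u)
    us = np.asarray(us)
    lo = (us <= u_obs).mean()
    hi = (us >= u_obs).mean()
    return u_obs, min(1.0, 2 * min(lo, hi))


class TestWrsTest:
    def test_separated_groups_exact(self):
        # all 20 assignments enumerable by hand: P(U<=0) = 1/20 per tail
        res = wrs_test([1, 2, 3], [4, 5, 6])
        assert res.u_statistic == 0.0
        assert res.p_value == pytest.approx(0.1, abs=1e-12)
        assert res.direction == UP_IN_GROUP2

    def test_fully_tied_data(self):
        res = wrs_test([2.0, 2.0, 2.0], [2.0, 2.0, 2.0])
        assert res.direction == TIED
        assert res.p_value == 1.0

    def test_swap_symmetry(self, rng):
        for _ in range(20):
            x = rng.normal(size=rng.integers(2, 10))
            y = rng.normal(size=rng.integers(2, 10))
            a, b = wrs_test(x, y), wrs_test(y, x)
            assert a.u_statistic + b.u_statistic == pytest.approx(len(x) * len(y))
            assert a.p_value == pytest.approx(b.p_value, rel=1e-12)

    def test_exact_branch_matches_enumeration(self, rng):
        for n1, n2 in [(2, 3), (4, 4), (5, 6), (6, 6)]:
            x = rng.normal(size=n1)
            y = rng.normal(size=n2)
            u_bf, p_bf = brute_force_wrs(x, y)
            res = wrs_test(x, y)
            assert res.u_statistic == pytest.approx(u_bf)
            assert res.p_value == pytest.approx(p_bf, abs=1e-12)

    def test_exact_branch_matches_scipy(self, rng):
        for _ in range(10):
            x = rng.normal(size=5)
            y = rng.normal(size=7)
            res = wrs_test(x, y)
            ref = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
            assert res.p_value == pytest.approx(ref.pvalue, abs=1e-12)

    def test_normal_approx_close_to_exact_at_n8(self, rng):
        # agreement of the two branches at the boundary sample size; the
        # continuity-corrected normal approximation deviates from the exact
        # distribution by at most ~0.011 (mid-range p) at n1=n2=8
        from mi2p.differential import _wrs_matrix

        for _ in range(200):
            x = rng.normal(size=8)
            y = rng.normal(size=8)
            exact = wrs_test(x, y).p_value
            _, p_approx, _ = _wrs_matrix(np.r_[x, y][None, :], 8)
            assert abs(exact - p_approx[0]) < 0.011

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            wrs_test([], [1.0])


class TestBhQvalues:
    def test_equal_spacing_example(self):
        # p*m/rank = 0.04 for every rank
        assert np.allclose(bh_qvalues([0.01, 0.02, 0.03, 0.04]), 0.04)

    def test_single_value(self):
        assert bh_qvalues([1.0]).tolist() == [1.0]

    def test_monotone_on_sorted_input(self, rng):
        p = np.sort(rng.uniform(size=50))
        q = bh_qvalues(p)
        assert (np.diff(q) >= -1e-15).all()

    def test_matches_independent_step_up(self, rng):
        def oracle(p):
            m = len(p)
            order = np.argsort(p)
            q = np.empty(m)
            prev = 1.0
            for rank in range(m, 0, -1):
                i = order[rank - 1]
                prev = min(prev, p[i] * m / rank)
                q[i] = prev
            return np.minimum(q, 1.0)

        for _ in range(50):
            p = rng.uniform(size=rng.integers(1, 40))
            assert np.allclose(bh_qvalues(p), oracle(p), atol=1e-14)

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.uniform(size=200)
        _, q_ref, _, _ = multipletests(p, method="fdr_bh")
        assert np.allclose(bh_qvalues(p), q_ref)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_qvalues([0.5, 1.5])


def _matrix_from_counts(counts, samples, k=3):
    from mi2p._encoding import canonical_codes_of_seqs
    from mi2p.kmers import build_matrix as _  # noqa: F401

    n = counts.shape[0]
    # n distinct canonical 3-mers as row ids
    codes = canonical_codes_of_seqs(
        ["AAA", "AAC", "AAG", "AAT", "ACA", "ACC", "ACG", "ACT", "AGA", "AGC"][:n], k
    )
    return KmerCountMatrix(
        k=k,
        codes=codes,
        samples=samples,
        counts=counts,
        sample_read_totals={s: 1_000_000 for s in samples},
    )


class TestSelectDifferentialKmers:
    def test_identical_rows_yield_empty_set(self):
        samples = [f"s{i}" for i in range(8)]
        labels = {s: ("case" if i < 4 else "control") for i, s in enumerate(samples)}
        counts = np.tile([5, 5, 5, 5, 5, 5, 5, 5], (4, 1))
        m = _matrix_from_counts(counts, samples)
        assert len(select_differential_kmers(m, labels)) == 0

    def test_permutation_invariance(self, rng):
        samples = [f"s{i}" for i in range(12)]
        labels = {s: ("case" if i < 6 else "control") for i, s in enumerate(samples)}
        counts = rng.integers(0, 50, size=(10, 12))
        m = _matrix_from_counts(counts, samples)
        sel = select_differential_kmers(m, labels, q_cutoff=0.8)
        cols = rng.permutation(12)
        m2 = KmerCountMatrix(
            k=m.k,
            codes=m.codes,
            samples=[samples[j] for j in cols],
            counts=counts[:, cols],
            sample_read_totals=m.sample_read_totals,
        )
        sel2 = select_differential_kmers(m2, labels, q_cutoff=0.8)
        assert set(sel.kmers) == set(sel2.kmers)

    def test_single_group_rejected(self):
        samples = ["a", "b", "c", "d"]
        m = _matrix_from_counts(np.ones((2, 4), dtype=int), samples)
        with pytest.raises(ValueError):
            select_differential_kmers(m, {s: "case" for s in samples})

    def test_membership_interface(self, rng):
        samples = [f"s{i}" for i in range(20)]
        labels = {s: ("case" if i < 10 else "control") for i, s in enumerate(samples)}
        counts = np.vstack(
            [
                np.r_[rng.integers(50, 60, 10), rng.integers(0, 5, 10)],
                rng.integers(10, 12, 20)[None, :].reshape(1, 20),
            ]
        )
        m = _matrix_from_counts(counts, samples)
        sel = select_differential_kmers(m, labels, q_cutoff=0.05)
        assert sel.kmers and sel.kmers[0] in sel
        entry = sel.entries[sel.kmers[0]]
        assert entry[0].direction == UP_IN_GROUP1
        assert entry[1] <= 0.05


class TestIdentifyAbundantKmers:
    def test_top_fraction_with_ties_broken_lexicographically(self, rng):
        samples = ["a", "b"]
        counts = np.arange(20)[::-1].reshape(10, 2)
        m = _matrix_from_counts(counts, samples)
        top = identify_abundant_kmers(m, top_quantile=0.2)
        # 2 of 10 kmers; rows are sorted by code and row 0 has the largest mean
        assert set(top.kmers) == set(m.kmers[:2])

    def test_uniform_matrix_deterministic_size(self):
        samples = ["a", "b", "c"]
        m = _matrix_from_counts(np.full((10, 3), 7), samples)
        top = identify_abundant_kmers(m, top_quantile=0.3)
        assert len(top) == 3
        assert top.kmers == m.kmers[:3]  # lexicographic tie-break

    def test_sample_order_invariance(self, rng):
        samples = ["a", "b", "c", "d"]
        counts = rng.integers(0, 100, (10, 4))
        m = _matrix_from_counts(counts, samples)
        top1 = identify_abundant_kmers(m, 0.25)
        m2 = KmerCountMatrix(
            k=m.k,
            codes=m.codes,
            samples=samples[::-1],
            counts=counts[:, ::-1],
            sample_read_totals=m.sample_read_totals,
        )
        top2 = identify_abundant_kmers(m2, 0.25)
        assert top1.kmers == top2.kmers
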