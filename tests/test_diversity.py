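"""Alpha-diversity indices, rarefaction, clustering pairing check and the
paired signed-rank test."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cytodm.diversity import (
    chao1,
    evenness,
    goods_coverage,
    paired_signed_rank,
    pairing_cluster_check,
    rarefaction_curve,
    shannon,
)
from cytodm.tables import OtuTable, SamplePairing

count_vectors = st.lists(st.integers(0, 50), min_size=1, max_size=25).filter(
    lambda v: sum(v) > 0
)


class TestShannon:
    def test_uniform(self):
        assert shannon([5, 5, 5, 5]) == pytest.approx(np.log(4))

    def test_single_taxon(self):
        assert shannon([10]) == 0.0

    def test_direct_summation_value(self):
        # frozen from -sum(p ln p), p = (1/6, 2/6, 3/6)
        assert shannon([1, 2, 3]) == pytest.approx(1.011404, abs=1e-6)

    def test_all_zero_raises(self):
        with pytest.raises(ValueError):
            shannon([0, 0])

    @settings(derandomize=True, max_examples=50)
    @given(count_vectors.filter(lambda v: sum(1 for x in v if x > 0) >= 2))
    def test_uniform_is_maximal_for_fixed_richness(self, v):
        r = sum(1 for x in v if x > 0)
        assert shannon(v) <= np.log(r) + 1e-12


class TestEvenness:
    def test_uniform_is_one(self):
        assert evenness([7, 7, 7]) == pytest.approx(1.0)

    def test_single_taxon_is_missing(self):
        assert np.isnan(evenness([10]))

    def test_derived_from_shannon(self):
        assert evenness([1, 2, 3]) == pytest.approx(1.011404 / np.log(3), abs=1e-6)


class TestChao1:
    @pytest.mark.parametrize(
        "counts,expected",
        [
            ([1, 1, 2, 3, 4], 7.0),       # S=5, F1=2, F2=1 -> 5 + 4/2
            ([3, 4, 5], 3.0),             # no singletons
            ([1, 1, 1, 3], 7.0),          # F1=3, F2=0 bias-corrected: 4 + 3*2/2
        ],
    )
    def test_formula(self, counts, expected):
        assert chao1(counts) == pytest.approx(expected)

    @settings(derandomize=True, max_examples=50)
    @given(count_vectors)
    def test_at_least_observed_richness(self, v):
        assert chao1(v) >= sum(1 for x in v if x > 0)


class TestGoodsCoverage:
    def test_formula(self):
        # 2 singleton taxa among 200 reads -> 99.0 %
        counts = [1, 1] + [99, 99]
        assert goods_coverage(counts) == pytest.approx(99.0)

    def test_no_singletons(self):
        assert goods_coverage([5, 7]) == 100.0

    def test_all_singletons(self):
        assert goods_coverage([1, 1, 1]) == 0.0

    @settings(derandomize=True, max_examples=50)
    @given(count_vectors)
    def test_bounded(self, v):
        assert 0.0 <= goods_coverage(v) <= 100.0


class TestRarefaction:
    def test_single_taxon_constant_curve(self):
        curve = rarefaction_curve([500], step=50)
        assert np.allclose(curve.expected_otus, 1.0)
        assert curve.final_slope == pytest.approx(0.0, abs=1e-12)
        assert curve.saturated

    def test_full_depth_equals_richness(self, rng):
        counts = rng.integers(1, 40, size=30)
        curve = rarefaction_curve(counts, step=50)
        assert curve.depths[-1] == counts.sum()
        assert curve.expected_otus[-1] == pytest.approx(30.0)

    @settings(derandomize=True, max_examples=30)
    @given(st.lists(st.integers(0, 30), min_size=2, max_size=15).filter(lambda v: sum(v) >= 10))
    def test_monotone_in_depth(self, v):
        curve = rarefaction_curve(v, step=3)
        assert np.all(np.diff(curve.expected_otus) >= -1e-9)

    def test_matches_multinomial_subsampling(self, rng):
        """Exact hypergeometric expectation vs a Monte-Carlo subsampling oracle:
        richness of random read subsets at every grid depth."""
        counts = rng.multinomial(10_000, rng.dirichlet(np.full(50, 0.3)))
        counts = counts[counts > 0]
        curve = rarefaction_curve(counts, step=2000)
        n_rep = 1000
        pool = np.repeat(np.arange(counts.size), counts)
        richness = np.empty((n_rep, curve.depths.size))
        for r in range(n_rep):
            shuffled = rng.permutation(pool)
            for d_idx, d in enumerate(curve.depths):
                richness[r, d_idx] = np.unique(shuffled[:d]).size
        for d_idx in range(curve.depths.size):
            se = richness[:, d_idx].std(ddof=1) / np.sqrt(n_rep)
            assert (
                abs(richness[:, d_idx].mean() - curve.expected_otus[d_idx])
                < 3 * max(se, 1e-3)
            )

    def test_step_larger_than_total(self):
        with pytest.raises(ValueError):
            rarefaction_curve([3, 2], step=50)


class TestPairingClusterCheck:
    def _table_and_pairing(self, counts):
        n = counts.shape[0]
        sids = [f"S{i}" for i in range(n)]
        pairing = SamplePairing(
            {f"P{i}": (sids[2 * i], sids[2 * i + 1]) for i in range(n // 2)}
        )
        return OtuTable(counts, sids, [f"O{j}" for j in range(counts.shape[1])], {}), pairing

    def test_identical_pairs_fraction_one(self, rng):
        half = rng.integers(0, 100, size=(10, 12))
        counts = np.repeat(half, 2, axis=0)
        table, pairing = self._table_and_pairing(counts)
        assert pairing_cluster_check(table, pairing) == 1.0

    def test_iid_null_fraction_low(self):
        """Unrelated samples rarely form direct merges (null simulation)."""
        below = 0
        n_rep = 50
        for seed in range(n_rep):
            r = np.random.default_rng(seed)
            counts = r.integers(0, 100, size=(80, 30))
            table, pairing = self._table_and_pairing(counts)
            if pairing_cluster_check(table, pairing) < 0.5:
                below += 1
        assert below >= int(0.95 * n_rep)

    def test_invariant_to_row_permutation(self, rng):
        counts = rng.integers(1, 50, size=(12, 8))
        table, pairing = self._table_and_pairing(counts)
        frac = pairing_cluster_check(table, pairing)
        perm = rng.permutation(12)
        shuffled = OtuTable(
            counts[perm], [table.sample_ids[i] for i in perm], table.taxon_ids, {}
        )
        assert pairing_cluster_check(shuffled, pairing) == frac

    def test_missing_sample_error(self, rng):
        table, _ = self._table_and_pairing(rng.integers(1, 9, size=(4, 3)))
        bad = SamplePairing({"P0": ("S0", "S1"), "P1": ("S2", "ABSENT")})
        with pytest.raises(ValueError, match="ABSENT"):
            pairing_cluster_check(table, bad)


class TestPairedSignedRank:
    def test_all_zero_differences_error(self):
        a = np.arange(6, dtype=float)
        with pytest.raises(ValueError, match="zero"):
            paired_signed_rank(a, a)

    def test_exact_p_constant_shift(self):
        """n=10 uniformly positive unit differences: p = 2/1024, the value an
        exhaustive enumeration of all 2^10 sign assignments gives."""
        b = np.linspace(1, 5, 10)
        stat, p = paired_signed_rank(b + 1.0, b)
        assert p == pytest.approx(2 / 1024)
        assert stat == pytest.approx(55.0)  # all ranks positive

    def test_exact_matches_brute_force_enumeration(self, rng):
        d = rng.normal(size=10)
        d[d == 0] = 0.5
        a = rng.normal(size=10)
        stat, p = paired_signed_rank(a + d, a)
        # independent oracle: enumerate every sign assignment of the midranks
        absd = np.abs(d)
        order = np.argsort(absd)
        ranks = np.empty(10)
        sr = absd[order]
        i = 0
        while i < 10:
            j = i
            while j + 1 < 10 and sr[j + 1] == sr[i]:
                j += 1
            ranks[order[i:j + 1]] = (i + j) / 2 + 1
            i = j + 1
        w_obs = ranks[d > 0].sum()
        dist = [sum(r for r, s in zip(ranks, signs) if s)
                for signs in itertools.product([False, True], repeat=10)]
        dist = np.array(dist)
        lower = np.mean(dist <= w_obs + 1e-9)
        upper = np.mean(dist >= w_obs - 1e-9)
        assert p == pytest.approx(min(1.0, 2 * min(lower, upper)), abs=1e-12)

    def test_swapping_inputs_flips_statistic(self, rng):
        a = rng.normal(size=12)
        b = a + rng.normal(size=12)
        s1, p1 = paired_signed_rank(a, b)
        s2, p2 = paired_signed_rank(b, a)
        assert s1 == -s2
        assert p1 == p2

    def test_scipy_agreement_without_ties(self, rng):
        from scipy.stats import wilcoxon

        a = rng.normal(size=15)
        b = a + rng.normal(size=15)
        _, p = paired_signed_rank(a, b)
        ref = wilcoxon(a, b, alternative="two-sided", method="exact")
        assert p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_large_n_normal_approximation(self, rng):
        a = rng.normal(size=60)
        b = a + 0.5 + rng.normal(size=60)
        _, p = paired_signed_rank(a, b)
        from scipy.stats import wilcoxon

        ref = wilcoxon(a, b, alternative="two-sided", correction=False, method="approx")
        assert p == pytest.approx(ref.pvalue, rel=1e-6)
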