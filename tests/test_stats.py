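"""Resampling engine and classical-test contracts against independent
oracles (enumeration, closed forms)."""

import math
from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, strategies as st

from m6dakit.stats import (
    ShuffleUniverse,
    bh_adjust,
    binomial_two_sided,
    empirical_pvalue,
    fisher_exact,
    hypergeometric_overlap,
    overlap_exact,
    overlap_windowed,
    proportions_test,
    ranksum,
    shuffle_sites,
)
from m6dakit.types import KineticSite, SiteSet


def _sites(keys):
    return SiteSet(KineticSite(c, p, s) for c, p, s in keys)


class TestEmpiricalPvalue:
    def test_floor_at_one_over_n(self):
        null = np.zeros(1000)
        assert empirical_pvalue(5.0, null) == 0.001

    def test_49_exceedances_gives_0_05(self):
        null = np.concatenate([np.full(49, 10.0), np.zeros(951)])
        assert empirical_pvalue(5.0, null) == pytest.approx(0.05)

    def test_capped_at_one(self):
        assert empirical_pvalue(-1.0, np.zeros(10)) == 1.0

    def test_super_uniform_under_null(self):
        # exchangeable draws: P(p <= alpha) <= alpha
        rng = np.random.default_rng(0)
        ps = []
        for _ in range(500):
            draws = rng.normal(size=101)
            ps.append(empirical_pvalue(draws[0], draws[1:]))
        ps = np.array(ps)
        for alpha in (0.05, 0.1, 0.25):
            assert (ps <= alpha).mean() <= alpha + 3 * math.sqrt(alpha / 500)

    def test_empty_null_errors(self):
        with pytest.raises(ValueError):
            empirical_pvalue(1.0, [])


class TestShuffle:
    def test_universe_equal_to_sites_permutes_positions(self):
        genome = {"chr1": "ATATATAT"}
        uni = ShuffleUniverse.from_genome(genome)
        sites = _sites([("chr1", p, "+") for p in (0, 2, 4, 6)]
                       + [("chr1", p, "-") for p in (1, 3, 5, 7)])
        shuffled = shuffle_sites(sites, uni, np.random.default_rng(0))
        assert set(shuffled.keys()) == set(sites.keys())

    def test_per_chromosome_counts_preserved(self, rng):
        genome = {"chr1": "A" * 200, "chr2": "T" * 300}
        uni = ShuffleUniverse.from_genome(genome)
        sites = _sites(
            [("chr1", p, "+") for p in range(17)]
            + [("chr2", p, "-") for p in range(29)]
        )
        for _ in range(5):
            sh = shuffle_sites(sites, uni, rng)
            counts = {c: len(sh.by_chrom(c)) for c in ("chr1", "chr2")}
            assert counts == {"chr1": 17, "chr2": 29}

    def test_inclusion_frequency_uniform(self):
        # 100-position universe, 10 sites, 1000 draws: every position is
        # included ~100 times (binomial error bars)
        genome = {"chr1": "A" * 100}
        uni = ShuffleUniverse.from_genome(genome)
        sites = _sites([("chr1", p, "+") for p in range(10)])
        rng = np.random.default_rng(5)
        freq = np.zeros(100)
        n_draws = 1000
        for _ in range(n_draws):
            for s in shuffle_sites(sites, uni, rng):
                freq[s.pos] += 1
        expected = n_draws * 10 / 100
        sd = math.sqrt(n_draws * 0.1 * 0.9)
        assert np.all(np.abs(freq - expected) < 5 * sd)

    def test_too_many_sites_errors(self):
        uni = ShuffleUniverse.from_genome({"chr1": "AC"})
        sites = _sites([("chr1", 0, "+"), ("chr1", 0, "-")])
        with pytest.raises(ValueError):
            shuffle_sites(sites, uni, np.random.default_rng(0))

    def test_exclusion_regions_removed(self):
        uni = ShuffleUniverse.from_genome(
            {"chr1": "A" * 100}, exclude={"chr1": [(0, 50)]}
        )
        assert uni.n_positions("chr1") == 50


class TestOverlaps:
    def test_exact_identity_and_disjoint(self):
        a = _sites([("chr1", 1, "+"), ("chr1", 2, "-")])
        b = _sites([("chr2", 1, "+"), ("chr2", 2, "-")])
        assert overlap_exact(a, a) == 2
        assert overlap_exact(a, b) == 0
        assert overlap_exact(a, b) == overlap_exact(b, a)

    def test_windowed_hand_example(self):
        # A={100}, B={300}, flank 250: intervals intersect -> one shared
        # region; exact overlap stays 0
        a = _sites([("chr1", 100, "+")])
        b = _sites([("chr1", 300, "+")])
        w = overlap_windowed(a, b, flank=250)
        assert (w.n_regions, w.members_a, w.members_b) == (1, 1, 1)
        assert overlap_exact(a, b) == 0
        far = _sites([("chr1", 2000, "+")])
        assert overlap_windowed(a, far, flank=250).n_regions == 0


class TestProportionsTest:
    def test_identical_proportions(self):
        stat, p = proportions_test([[50, 50], [50, 50]])
        assert stat == 0.0 and p == 1.0

    def test_matches_hand_computed_yates_chi2(self):
        # 30/100 vs 10/100, textbook continuity-corrected chi-squared:
        # chi2 = N(|ad - bc| - N/2)^2 / (r1 r2 c1 c2)
        a, b, c, d = 30, 70, 10, 90
        n = a + b + c + d
        chi2_hand = n * (abs(a * d - b * c) - n / 2) ** 2 / (
            (a + b) * (c + d) * (a + c) * (b + d)
        )
        stat, p = proportions_test([[a, b], [c, d]])
        assert stat == pytest.approx(chi2_hand)
        from scipy.stats import chi2 as chi2_dist

        assert p == pytest.approx(chi2_dist.sf(chi2_hand, 1))

    def test_k_by_2_without_correction(self):
        stat, _ = proportions_test([[30, 70], [10, 90], [20, 80]])
        assert stat > 0

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            proportions_test([[1, -1], [2, 3]])


class TestFisherAndHypergeometric:
    @pytest.mark.parametrize(
        "table",
        [
            [[5, 10], [12, 3]],
            [[0, 20], [10, 10]],
            [[25, 25], [25, 25]],
            [[3, 0], [0, 4]],
        ],
    )
    def test_fisher_matches_hypergeometric_tail_enumeration(self, table):
        """Two-sided Fisher p equals the sum of hypergeometric probabilities
        of all tables (same margins) no more likely than the observed one."""
        (a, b), (c, d) = table
        r1, c1, n = a + b, a + c, a + b + c + d

        def prob(x):
            return (
                math.comb(r1, x)
                * math.comb(n - r1, c1 - x)
                / math.comb(n, c1)
            )

        p_obs = prob(a)
        p_enum = sum(
            prob(x)
            for x in range(max(0, c1 - (n - r1)), min(r1, c1) + 1)
            if prob(x) <= p_obs * (1 + 1e-9)
        )
        _, p = fisher_exact(table)
        assert p == pytest.approx(p_enum, rel=1e-9)

    def test_hypergeometric_overlap_matches_enumeration(self):
        """Upper-tail overlap p equals brute-force enumeration of draws for
        universes up to 30."""
        for universe, n_a, n_b, k in [(30, 10, 12, 7), (20, 5, 8, 3), (12, 6, 6, 6)]:
            total = 0.0
            hit = 0.0
            for drawn in combinations(range(universe), n_b):
                ov = sum(1 for x in drawn if x < n_a)
                total += 1
                if ov >= k:
                    hit += 1
            assert hypergeometric_overlap(n_a, n_b, k, universe) == pytest.approx(
                hit / total, rel=1e-9
            )

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            hypergeometric_overlap(10, 10, 11, 30)


class TestBinomialAndBH:
    def test_symmetric_center_is_one(self):
        assert binomial_two_sided(5, 10) == pytest.approx(1.0)

    def test_extreme_closed_form(self):
        assert binomial_two_sided(100, 100) == pytest.approx(2 * 0.5**100)
        assert binomial_two_sided(0, 100) == pytest.approx(2 * 0.5**100)

    @given(
        st.lists(st.floats(min_value=1e-12, max_value=1.0), min_size=1, max_size=40)
    )
    def test_bh_dominates_p_and_is_monotone(self, ps):
        q = bh_adjust(ps)
        assert np.all(q >= np.asarray(ps) - 1e-12)
        assert np.all(q <= 1.0 + 1e-12)
        order = np.argsort(ps)
        assert np.all(np.diff(q[order]) >= -1e-12)

    def test_ranksum_requires_data(self):
        with pytest.raises(ValueError):
            ranksum([], [1.0])
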