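"""Haplotype-resolved calling, differential methylation, and trio tests."""

import math

import numpy as np
import pandas as pd
import pytest

from m6dakit.calling import CallingParams
from m6dakit.haplotypes import (
    differential_gene_methylation,
    haplotype_exclusivity,
    regress_diploid_on_haplotypes,
    split_and_call_by_haplotype,
    strand_coverage_filter,
    trio_analysis,
)
from m6dakit.simulate import SimulationConfig, generate_genome, simulate_trio
from m6dakit.types import KineticSite, MoleculeObservation, SiteSet

PARAMS = CallingParams(mu0=0.0, sigma=0.5, delta=math.log(16))


def _site_molecules(pos, hp1_meth, hp2_meth, cov_per_hap=25, untagged=0, rng=None):
    """Molecules at one site: each haplotype fully methylated or not."""
    rng = rng or np.random.default_rng(pos)
    out = []
    mid = 0
    for tag, meth in (("HP1", hp1_meth), ("HP2", hp2_meth)):
        for _ in range(cov_per_hap):
            x = rng.normal(PARAMS.delta if meth else 0.0, 0.05)
            out.append(MoleculeObservation("chr1", pos, "+", mid, x, 10, tag))
            mid += 1
    for _ in range(untagged):
        out.append(MoleculeObservation("chr1", pos, "+", mid, 0.0, 10, "untagged"))
        mid += 1
    return out


class TestSplitAndCall:
    def test_hp1_only_methylation_dilutes_diploid(self):
        calls = split_and_call_by_haplotype(
            _site_molecules(100, True, False), PARAMS
        )
        row = calls.table.iloc[0]
        assert row["hp1_fraction"] == pytest.approx(1.0, abs=0.02)
        assert row["hp2_fraction"] == pytest.approx(0.0, abs=0.02)
        assert row["diploid_fraction"] == pytest.approx(0.5, abs=0.05)
        assert ("chr1", 100, "+") in calls.hp1_called
        assert ("chr1", 100, "+") not in calls.hp2_called

    def test_identical_haplotypes_are_symmetric(self):
        calls = split_and_call_by_haplotype(_site_molecules(7, True, True), PARAMS)
        row = calls.table.iloc[0]
        assert row["hp1_fraction"] == pytest.approx(row["hp2_fraction"], abs=0.02)

    def test_coverage_sums_across_tags(self):
        mols = _site_molecules(5, True, False, cov_per_hap=20, untagged=13)
        calls = split_and_call_by_haplotype(mols, PARAMS)
        row = calls.table.iloc[0]
        assert row["hp1_coverage"] + row["hp2_coverage"] + 13 == row["diploid_coverage"]

    def test_all_untagged_errors(self):
        mols = [MoleculeObservation("chr1", 1, "+", i, 0.0, 5) for i in range(10)]
        with pytest.raises(ValueError):
            split_and_call_by_haplotype(mols, PARAMS)

    def test_inclusion_requires_20x_per_haplotig(self):
        calls = split_and_call_by_haplotype(
            _site_molecules(9, True, False, cov_per_hap=15), PARAMS
        )
        assert not calls.table.iloc[0]["included"]


class TestExclusivity:
    def _ss(self, positions):
        return SiteSet(KineticSite("chr1", p, "+", 30, 8.0, 1.0) for p in positions)

    def test_identical_call_sets(self):
        a = self._ss(range(10))
        res = haplotype_exclusivity(a, self._ss(range(10)))
        assert (res.hp1_only, res.hp2_only, res.both) == (0, 0, 10)

    def test_disjoint_call_sets(self):
        res = haplotype_exclusivity(self._ss(range(5)), self._ss(range(10, 15)))
        assert res.both == 0 and res.single_haplotype_fraction == 1.0


class TestRegression:
    def _table(self, h1, h2, dip):
        n = len(h1)
        return pd.DataFrame(
            {
                "chrom": ["chr1"] * n,
                "pos": range(n),
                "strand": ["+"] * n,
                "diploid_fraction": dip,
                "diploid_coverage": [40] * n,
                "hp1_fraction": h1,
                "hp1_coverage": [20] * n,
                "hp2_fraction": h2,
                "hp2_coverage": [20] * n,
                "included": [True] * n,
            }
        )

    def test_exact_mean_recovers_half_half(self, rng):
        h1, h2 = rng.random(200), rng.random(200)
        res = regress_diploid_on_haplotypes(self._table(h1, h2, (h1 + h2) / 2))
        coefs = res.set_index("term")["coef"]
        assert coefs["hp1_fraction"] == pytest.approx(0.5, abs=1e-9)
        assert coefs["hp2_fraction"] == pytest.approx(0.5, abs=1e-9)
        assert coefs["intercept"] == pytest.approx(0.0, abs=1e-9)

    def test_diploid_equals_hp1(self, rng):
        h1, h2 = rng.random(100), rng.random(100)
        res = regress_diploid_on_haplotypes(self._table(h1, h2, h1))
        coefs = res.set_index("term")["coef"]
        assert coefs["hp1_fraction"] == pytest.approx(1.0, abs=1e-9)
        assert coefs["hp2_fraction"] == pytest.approx(0.0, abs=1e-9)

    def test_noisy_recovery_within_band(self, rng):
        h1, h2 = rng.random(500), rng.random(500)
        dip = 0.5 * h1 + 0.5 * h2 + rng.normal(0, 0.05, 500)
        res = regress_diploid_on_haplotypes(self._table(h1, h2, dip))
        coefs = res.set_index("term")["coef"]
        assert coefs["hp1_fraction"] == pytest.approx(0.5, abs=0.05)
        assert coefs["hp2_fraction"] == pytest.approx(0.5, abs=0.05)
        assert (res.set_index("term")["pvalue"][["hp1_fraction", "hp2_fraction"]] < 1e-6).all()

    def test_collinear_design_errors(self):
        h = np.linspace(0, 1, 50)
        with pytest.raises(ValueError, match="collinear"):
            regress_diploid_on_haplotypes(self._table(h, h * 0 + 0.3, h))

    def test_too_few_sites_errors(self):
        with pytest.raises(ValueError):
            regress_diploid_on_haplotypes(self._table([0.1], [0.2], [0.15]))


class TestDifferentialMethylation:
    def _ss(self, fracs, cov=100):
        return SiteSet(
            KineticSite("chr1", p, "+", cov, 8.0, f) for p, f in enumerate(fracs)
        )

    def test_identical_samples_are_null(self):
        a = self._ss([0.4, 0.8, 0.6])
        gene_of = {k: "g1" for k in a.keys()}
        res = differential_gene_methylation(a, self._ss([0.4, 0.8, 0.6]), gene_of)
        assert (res["pvalue"] == 1.0).all()

    def test_hand_checkable_contrast(self):
        a = self._ss([0.8])  # 80 of 100 methylated
        b = self._ss([0.2])  # 20 of 100
        gene_of = {("chr1", 0, "+"): "g1"}
        res = differential_gene_methylation(a, b, gene_of)
        assert res.loc[0, ["meth_a", "cov_a", "meth_b", "cov_b"]].tolist() == [80, 100, 20, 100]
        assert res.loc[0, "pvalue"] < 0.001

    def test_symmetric_in_samples(self, rng):
        a = self._ss(rng.random(6))
        b = self._ss(rng.random(6))
        gene_of = {k: f"g{k[1] % 2}" for k in a.keys()}
        p_ab = differential_gene_methylation(a, b, gene_of)["pvalue"]
        p_ba = differential_gene_methylation(b, a, gene_of)["pvalue"]
        assert np.allclose(p_ab, p_ba)

    def test_bh_column_monotone(self, rng):
        a = self._ss(rng.random(40))
        b = self._ss(rng.random(40))
        gene_of = {k: f"g{k[1] % 10}" for k in a.keys()}
        res = differential_gene_methylation(a, b, gene_of).sort_values("pvalue")
        assert (res["qvalue"] >= res["pvalue"] - 1e-12).all()


class TestTrio:
    def test_identical_sets_overlap_fully(self):
        s = SiteSet(KineticSite("chr1", p, "+", 40, 8.0, 0.9) for p in range(50))
        pool = SiteSet(KineticSite("chr1", p, "+", 15, 2.0, 0.1) for p in range(100, 400))
        sites = {n: s for n in ("mother", "father", "son")}
        pools = {n: pool for n in ("mother", "father", "son")}
        res = trio_analysis(sites, pools, n_perm=50, seed=0)
        assert all(v == 50 for v in res.overlaps.values())
        assert all(p == pytest.approx(1 / 50) for p in res.permutation_p.values())

    def test_pool_smaller_than_calls_errors(self):
        s = SiteSet(KineticSite("chr1", p, "+", 40, 8.0, 0.9) for p in range(50))
        tiny = SiteSet([KineticSite("chr1", 999, "+", 15, 2.0, 0.1)])
        with pytest.raises(ValueError):
            trio_analysis(
                {n: s for n in ("mother", "father", "son")},
                {n: tiny for n in ("mother", "father", "son")},
                n_perm=10,
            )

    def test_zero_inheritance_is_null(self):
        cfg0 = SimulationConfig(seed=0)
        genome, _, _ = generate_genome(cfg0)
        trio = simulate_trio(genome, SimulationConfig(seed=0, inheritance_p=0.0))
        res = trio_analysis(trio.sites, trio.pools, n_perm=0)
        assert (res.relatedness["pvalue"] > 0.05).all()

    def test_inheritance_detected(self):
        cfg0 = SimulationConfig(seed=0)
        genome, _, _ = generate_genome(cfg0)
        trio = simulate_trio(genome, SimulationConfig(seed=0, inheritance_p=0.5))
        res = trio_analysis(trio.sites, trio.pools, n_perm=100, seed=1)
        # parent-son overlaps exceed the unrelated parent-parent overlap
        assert res.overlaps[("mother", "son")] > res.overlaps[("mother", "father")]
        assert (res.relatedness["pvalue"] < 0.001).all()
        assert res.permutation_p[("mother", "son")] == pytest.approx(1 / 100)


def test_strand_coverage_filter_rounding():
    # published family coverages 27x / 29x / 67x: half-coverage rounds
    # half-up to 14 / 15 / 34 (the 33x variant needs round-half-down,
    # which is why the filter stays overridable)
    assert strand_coverage_filter(27) == 14
    assert strand_coverage_filter(29) == 15
    assert strand_coverage_filter(67) == 34
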