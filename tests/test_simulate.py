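"""Generator contracts: determinism, planted structure, kinetic model."""

import math

import numpy as np
import pandas as pd
import pytest

from m6dakit import io as mio
from m6dakit.annotate import build_label_map
from m6dakit.simulate import (
    SimulationConfig,
    generate_genome,
    plant_m6dA,
    simulate_kinetics,
    simulate_phased_snps,
    simulate_trio,
)


class TestGenomeGeneration:
    def test_same_seed_is_byte_identical(self, tiny_config):
        g1, ann1, cr1 = generate_genome(tiny_config)
        g2, ann2, cr2 = generate_genome(tiny_config)
        assert g1 == g2 and cr1 == cr2
        assert ann1.transcripts == ann2.transcripts

    def test_zero_genes_gives_intergenic_only(self):
        cfg = SimulationConfig(seed=1, n_genes=0, n_clusters=0)
        genome, ann, _ = generate_genome(cfg)
        assert ann.transcripts == []
        lm = build_label_map(ann)
        assert all((lab == 6).all() for lab in lm.labels.values())  # intergenic code

    def test_genes_do_not_overlap(self):
        cfg = SimulationConfig(seed=4)
        _, ann, _ = generate_genome(cfg)
        for chrom in ann.chrom_sizes:
            spans = sorted((t.start, t.end) for t in ann.by_chrom(chrom))
            for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
                assert e1 <= s2

    def test_infeasible_packing_errors(self):
        cfg = SimulationConfig(seed=1, chrom_sizes={"chr1": 30_000}, n_genes=50)
        with pytest.raises(ValueError, match="pack"):
            generate_genome(cfg)

    def test_cluster_regions_reach_target_at_content(self):
        # 20 cluster regions x 500 bp = 10 kb of AT-enriched sequence
        cfg = SimulationConfig(seed=2, n_clusters=20)
        genome, _, cr = generate_genome(cfg)
        at = tot = 0
        for chrom, regions in cr.items():
            for a, b in regions:
                seq = genome[chrom][a:b]
                at += seq.count("A") + seq.count("T")
                tot += len(seq)
        assert tot >= 10_000
        assert at / tot == pytest.approx(cfg.cluster_at, abs=0.05)


class TestPlanting:
    def test_sites_sit_on_strand_specific_adenosines(self, sim):
        for r in sim.true_sites.head(300).itertuples(index=False):
            base = sim.genome[r.chrom][r.pos]
            assert base == ("A" if r.strand == "+" else "T")

    def test_unbiased_planting_matches_background_motif_rate(self):
        cfg = SimulationConfig(
            seed=6, motif_bias=1.0, n_clusters=0,
            feature_bias={f: 1.0 for f in
                          ("promoter", "utr5", "utr3", "exon", "intron",
                           "downstream", "intergenic")},
        )
        genome, ann, cr = generate_genome(cfg)
        df = plant_m6dA(genome, ann, cfg, cr)
        # background AG/GA rate among all adenosines: immediate neighbor is G
        # on the site strand with probability 1 - (3/4)^2
        p0 = 1 - 0.75**2
        rate = df["has_ag_ga"].mean()
        se = math.sqrt(p0 * (1 - p0) / len(df))
        assert rate == pytest.approx(p0, abs=4 * se)

    def test_full_spike_gives_fraction_one(self):
        cfg = SimulationConfig(seed=3, spike_weight=1.0,
                               hap_restricted_prop=0.0, n_clusters=0)
        genome, ann, cr = generate_genome(cfg)
        df = plant_m6dA(genome, ann, cfg, cr)
        assert (df["fraction"] == 1.0).all()

    def test_restricted_sites_have_half_diploid_fraction(self, sim):
        df = sim.true_sites
        restricted = df[df["hap"] != 0]
        assert np.allclose(restricted["fraction"], restricted["hap_fraction"] / 2)

    def test_cluster_regions_hold_at_least_ten_sites(self, sim):
        for chrom, regions in sim.cluster_regions.items():
            for a, b in regions:
                in_region = sim.true_sites.query(
                    "chrom == @chrom and @a <= pos < @b"
                )
                assert len(in_region) >= 10

    def test_excessive_density_errors(self):
        cfg = SimulationConfig(seed=1, m6dA_density=1.5)
        genome, ann, cr = generate_genome(cfg)
        with pytest.raises(ValueError, match="density"):
            plant_m6dA(genome, ann, cfg, cr)


class TestKinetics:
    def _df(self, positions, fraction, genome_len=2000):
        return pd.DataFrame(
            {
                "chrom": "chr1",
                "pos": positions,
                "strand": "+",
                "in_cluster": False,
                "has_ag_ga": False,
                "hap_fraction": fraction,
                "hap": 0,
                "fraction": fraction,
            }
        )

    def test_null_sites_have_unit_ipd_ratio(self):
        cfg = SimulationConfig(seed=9, spot_check_density=0.0)
        genome = {"chr1": "A" * 2000}
        df = self._df(list(range(50, 1050, 20)), 0.0)
        _, summaries = simulate_kinetics(df, genome, cfg)
        ratios = np.array([s.ipd_ratio for s in summaries])
        # per-site 4-sigma band: sd of mean log IPD ~ sigma / sqrt(cov * n_passes)
        band = 4 * cfg.sigma / math.sqrt(cfg.coverage_mean * cfg.n_passes_mean)
        assert np.all(ratios < math.exp(band) + 0.1)
        assert np.all(ratios > math.exp(-band) - 0.1)

    def test_fully_methylated_sites_hit_expected_ratio(self):
        cfg = SimulationConfig(seed=9, delta=math.log(4), spot_check_density=0.0)
        genome = {"chr1": "A" * 2000}
        df = self._df(list(range(50, 1050, 20)), 1.0)
        _, summaries = simulate_kinetics(df, genome, cfg)
        ratios = np.array([s.ipd_ratio for s in summaries])
        band = 4 * cfg.sigma / math.sqrt(cfg.coverage_mean * cfg.n_passes_mean)
        assert np.all(ratios < 4 * math.exp(band) + 0.1)
        assert np.all(ratios > 4 * math.exp(-band) - 0.1)

    def test_contexts_center_on_adenosine(self, sim):
        for s in list(sim.summaries)[:200]:
            if s.context is not None:
                assert len(s.context) == 41 and s.context[20] == "A"

    def test_emitted_files_reparse_losslessly(self, tiny_config, tmp_path):
        from m6dakit.simulate import simulate_bundle

        bundle = simulate_bundle(tiny_config, str(tmp_path))
        back = mio.read_modifications(str(tmp_path / "kinetics.tsv"), "tabular")
        assert back == bundle.site_summaries
        genome = mio.read_genome(str(tmp_path / "genome.fa"))
        assert genome == bundle.genome
        ann = mio.read_annotation(str(tmp_path / "genes.gff3"))
        assert ann.transcripts == bundle.annotation.transcripts


class TestHaplotypesAndTrio:
    def test_snp_rate_zero_errors(self):
        cfg = SimulationConfig(seed=1, snp_rate=0.0)
        with pytest.raises(ValueError):
            simulate_phased_snps({"chr1": "ACGT"}, cfg)

    def test_snps_are_heterozygous_and_phased(self):
        cfg = SimulationConfig(seed=1)
        genome = {"chr1": "ACGT" * 2000}
        snps = simulate_phased_snps(genome, cfg)
        assert len(snps) > 0
        assert (snps["hp1"] != snps["hp2"]).all()
        for r in snps.head(50).itertuples(index=False):
            assert genome[r.chrom][r.pos] == r.ref
            assert {r.hp1, r.hp2} == {r.ref, r.alt}

    def test_trio_sets_have_configured_size(self, tiny_config):
        genome, _, _ = generate_genome(tiny_config)
        trio = simulate_trio(genome, tiny_config)
        for name in ("mother", "father"):
            assert len(trio.sites[name]) == tiny_config.trio_n_sites
            assert len(trio.pools[name]) >= len(trio.sites[name])

    def test_pool_sites_fail_calling_filters(self, tiny_config):
        from m6dakit.calling import CallingParams, filter_sites

        genome, _, _ = generate_genome(tiny_config)
        trio = simulate_trio(genome, tiny_config)
        called, _ = filter_sites(trio.pools["mother"], CallingParams())
        assert len(called) == 0
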