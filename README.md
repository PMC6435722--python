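# m6dakit

Genome-wide characterization of **N6-methyldeoxyadenosine (6mA / m6dA)**
from single-molecule real-time (SMRT) sequencing kinetics.

6mA is a rare DNA modification in eukaryotic genomes. SMRT sequencing
detects it at single-nucleotide, single-strand resolution: a methylated
adenosine slows the polymerase, lengthening the inter-pulse duration (IPD)
between base incorporations. The ratio of observed to expected IPD — the
**IPD ratio** — rises to roughly 4 and above at methylated adenosines, and
because each circular-consensus molecule is an unamplified genomic fragment,
the share of molecules carrying the mark at a position (the **methylated
fraction**) measures epigenetic heterogeneity within a cell population.

`m6dakit` is a library and CLI for epigenomics researchers analysing such
kinetic data. It covers:

* **Site calling** — coverage ≥ 20× and IPD ratio ≥ 4 per strand-specific
  adenosine; methylated fractions from a fixed-means two-component Gaussian
  mixture on per-molecule mean log IPD (EM on the mixing weight), with the
  failed-filter records (coverage ≥ 11×) retained as a motif null set.
* **Annotation & enrichment** — one feature label per site under the
  precedence promoter > 5′UTR > 3′UTR > exon > intron > downstream >
  intergenic (promoter = 1 kb upstream of the TSS), per-chromosome and
  per-bin m6dA/dA ratios, and permutation fold-enrichment per feature
  (1,000 genome shuffles over the strand-specific dA universe; empirical
  p = (exceedances + 1)/N, so the floor at N = 1,000 is 0.001).
* **Clusters** — regions of 500 bp containing ≥ 10 sites (merged seed
  windows, oracle-checked against exhaustive window enumeration), their A/T
  content and inter-site spacing, abundance significance by shuffle, and
  cluster-vs-single contrasts (proportion tests per feature, rank-sum on
  methylated fraction).
* **Motifs** — Fisher's exact enrichment of the 16 dinucleotides adjacent
  to the methylated A against the failed-filter null, plus merged 3-mer /
  chained 4-mer combinations of overlapping significant dinucleotides.
* **Haplotypes & families** — per-haplotype calling from phased molecule
  tags with the 20×-per-haplotig inclusion rule, haplotype-exclusivity
  counts, OLS regression of diploid on haplotype fractions, per-gene
  differential methylation (pooled methylated-molecule counts, chi-squared
  proportions test, Benjamini–Hochberg), and trio overlap/permutation/
  relatedness tests.
* **Expression link** — TPM comparisons for genes with vs without 6mA
  (rank-sum), allele-specific expression by two-sided binomial test with BH
  control, and the hypergeometric overlap of ASE genes with
  haplotype-differentially-methylated genes.
* **Synthetic data** — a fully ground-truthed generator (toy genome, gene
  models, log-normal per-molecule kinetics with a methylation shift, AG/GA
  motif bias, feature bias, AT-rich clusters, SNP-phased haplotypes, trio
  inheritance, expression coupling) so every stage is testable without any
  external download.

## Worked example

```python
from m6dakit.simulate import SimulationConfig, simulate_bundle
from m6dakit.calling import CallingParams, filter_sites
from m6dakit.clusters import detect_clusters, clustered_fraction

cfg = SimulationConfig(seed=1)
bundle = simulate_bundle(cfg)            # genome, genes, kinetics, trio, ...

params = CallingParams(mu0=cfg.mu0, sigma=cfg.sigma, delta=cfg.delta)
called, null_set = filter_sites(bundle.site_summaries, params)
print(f"called {len(called)} sites (coverage >= 20, IPD ratio >= 4); "
      f"null set {len(null_set)}")

clusters, singles = detect_clusters(called)
print(f"{len(clusters)} clusters hold "
      f"{100 * clustered_fraction(called, clusters):.1f}% of called sites")
```

prints

```
called 804 sites (coverage >= 20, IPD ratio >= 4); null set 3211
8 clusters hold 13.1% of called sites
```

— of the simulated kinetic records, 804 pass both calling thresholds, and
the planted dense regions are recovered as 8 clusters holding ~13% of calls.
Motif enrichment against the failed-filter null recovers the planted AG/GA
preference; under homogeneous-methylation conditions
(`SimulationConfig(seed=1, n_clusters=0, spike_weight=1.0,
hap_restricted_prop=0.0)`) the two top-ranked dinucleotides print as

```
motif AG: odds ratio 2.29, p = 6.67e-24
motif GA: odds ratio 2.21, p = 1.79e-22
```

The same stages are available from the shell:

```bash
m6dakit simulate --seed 1 --out bundle/
m6dakit run-all --bundle bundle/ --out results/ --seed 1 --n-perm 1000
```

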