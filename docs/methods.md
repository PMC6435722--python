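# Methods

This note documents the models, conventions and design choices behind
`m6dakit`, and what the synthetic-data generator does and does not emulate.

## Kinetic model and fraction estimation

Per-molecule mean log IPD at a site is modelled as

    x_i ~ Normal(mu0 + delta * z_i, sigma^2 / n_passes_i)

where `z_i` is the molecule's methylation indicator, `mu0` the unmethylated
log-IPD level (default 0 on the log scale, i.e. ratios are relative),
`sigma` the per-pass log-IPD standard deviation (default 0.5, a typical
dispersion for multiplicative kinetic noise) and `delta` the methylation
shift. The site-level IPD ratio is `exp(mean_i(x_i) - mu0)`, the
exponential of the average log shift, so at a site with methylated fraction
f the expected log ratio is `f * delta`.

The default `delta = log 16` is chosen so that a site methylated on only
one of two haplotypes (diploid fraction 0.5) still reaches the site-level
IPD-ratio threshold of 4 in expectation (`exp(delta/2) = 4`); a fully
methylated site then shows a ratio of ~16, within the range reported for
6mA-induced polymerase slowdown. Examples and tests that state another
shift (e.g. `delta = log 4`) pass it explicitly.

The methylated fraction is the mixing weight of a two-component normal
mixture with both component means fixed (`mu0`, `mu0 + delta`) and
per-molecule variances `sigma^2 / n_passes`; only the weight is estimated,
by EM to absolute tolerance 1e-8 (cap 500 iterations, error on
non-convergence). With well-separated components the EM weight equals the
realized methylated-molecule share, so the error against the *planted*
fraction is binomial-sampling limited: RMSE ~ sqrt(E[f(1-f)]/coverage),
about 0.07 at 40x — this is what the fraction-recovery checks measure.
When per-molecule records are absent a method-of-moments fallback
`f = (ratio - 1)/(exp(delta) - 1)`, clamped to [0, 1], is provided.

Methylated molecule counts are `round-half-up(fraction * coverage)`;
half-up is fixed for cross-platform determinism.

## Calling thresholds

Called sites require coverage >= 20 and IPD ratio >= 4.0, both inclusive
(the two inequalities are reported with mixed strictness in the literature;
inclusive bounds are reproducible and configurable via `CallingParams`).
Records failing either criterion but with coverage >= 11 form the
failed-filter null set used as the motif background; lower-coverage records
are dropped. Both strands of a genomic position are distinct sites
throughout — SMRT sequencing reads each strand separately.

## Feature assignment and enrichment

Each genomic position receives exactly one label with precedence
promoter > 5'UTR > 3'UTR > exon > intron > downstream (<= 1 kb past the
transcript end) > intergenic; ties within one class go to the lowest gene
id. Promoters are 1 kb upstream of the TSS. Labels are painted into
per-chromosome arrays, which makes per-feature dA denominators and shuffle
lookups O(1). The dA denominator is strand-specific (a reference A and a
reference T are each one assayable adenosine); a strand-collapsed mode
(reference A only) exists behind a flag. An optional exclusion BED
(e.g. centromeres) is applied before all ratio computations.

Fold enrichment per feature is `(m6dA_f/dA_f) / (m6dA_tot/dA_tot)`; its
significance comes from re-placing the same per-chromosome site counts
uniformly on the dA universe and comparing `|fold - 1|` (two-sided),
1,000 shuffles by default.

## Permutation convention

Empirical p-values are `(exceedances + 1)/N`, floored at `1/N` — exactly
0.001 at 1,000 shuffles with no null exceedance. This convention is
super-uniform under the null (verified by simulation). Shuffles preserve
per-chromosome counts by default; a genome-wide mode exists behind a flag.

## Clusters

A cluster seed is a 500 bp window anchored at a site position containing at
least 10 sites (strands pooled by position); overlapping seeds merge into
maximal clusters, and every site inside a merged span is a member.
Anchoring windows at site positions is equivalent in membership to
enumerating every integer window start (any qualifying window can be slid
right onto its leftmost site without losing members), which is what the
brute-force oracle in the tests does. Merging avoids double-counting of
overlapping qualifying windows. Cluster abundance significance uses the
fraction of sites in clusters as statistic against shuffled-and-reclustered
null draws.

## Motifs

A site *has* dinucleotide XY iff XY equals (upstream neighbor + A) or
(A + downstream neighbor) on the site's strand; all 16 dinucleotides are
tested by two-sided Fisher's exact against the failed-filter null, with
Bonferroni at alpha = 0.05 across the 16 tests (configurable). Two-sided is
the default because enrichment direction is not assumed. A windowed mode
(occurrence anywhere in the 41-base context) exists behind a flag.

Combination of significant dinucleotides is ambiguous in the source
procedure; the implemented default merges every ordered overlapping pair
(d1[1] == d2[0]) into a 3-mer core and every chained triple into a 4-mer
(GA + AG -> GAG, GAGA, ...), and a context carries a combined motif iff the
motif occurs covering the central A with one of its own A positions aligned
at the center. The alternative reading (extending the window around the
merged pair) is not implemented.

## Haplotypes and families

Molecules tagged HP1/HP2 are called independently per haplotype and pooled
(diploid); untagged molecules contribute to diploid calls only. The
haplotype table applies the inclusion rule: found in the diploid analysis
and >= 20x coverage on each haplotig. The diploid~haplotype relation is
ordinary least squares of diploid fraction on (HP1, HP2) fractions with
intercept; with balanced coverage the construction weights are (0.5, 0.5).

Haplotype exclusivity is reported two ways. The raw partition of the two
call sets (HP1-only / HP2-only / both) mirrors the usual Venn-style
summary but is inflated near the calling threshold: an unrestricted site
with fraction ~0.5 on both haplotypes randomly clears the threshold on one
side only. The calibrated measure (`single_haplotype_fraction`) therefore
counts a one-haplotype call as exclusive only when the partner haplotig has
informative coverage and an estimated fraction below 0.25 — i.e. no
methylation evidence rather than a near-miss of the call threshold. On
ground-truthed data this recovers the planted exclusivity within +/- 0.02.

Per-gene differential methylation sums methylated-molecule counts and
coverages over the union of positions methylated in either sample, then
applies the continuity-corrected chi-squared proportions test with BH
adjustment across genes.

Trio analysis computes pairwise exact overlaps; permutation significance
draws same-sized random sets from each member's failed-filter pool. The
relatedness test is deliberately asymmetric, comparing the proportion of
the parent's sites shared with the other parent against the proportion of
the *son's* sites shared with that parent (2x2 chi-squared), which accounts
for unequal set sizes. Strand-specific coverage floors for family samples
are round-half-up of half the genome coverage, overridable per individual
because published floors mix both rounding directions. Under zero
inheritance the test is conservative in this generator (empirical type-I
~0.01-0.03 at nominal 0.05): the shared conserved-site pool and the fixed
per-member set size reduce the overlap variance below the binomial
variance the chi-squared test assumes. It never exceeds its nominal level.

## Expression link

Genes are split by presence of a called site in a named feature (or the
gene-level union) and compared by two-sided rank-sum on TPM — rank-based,
hence invariant to monotone rescaling. ASE is a two-sided binomial test of
hap1 counts against 0.5 with BH control over genes with phased depth >= 20
(the depth floor is a package choice; no published value exists). The ASE
set is intersected with haplotype-differentially-methylated genes under an
upper-tail hypergeometric test on the tested-gene universe.

## Synthetic-data generator

One integer seed drives independent named substreams per stage (genome,
genes, planting, kinetics, SNPs, trio, expression), so adding a stage never
perturbs earlier draws and every output is byte-reproducible.

Defaults and rationale:

* Genome: 3 chromosomes x 200 kb, uniform base composition; 30
  non-overlapping genes (2-5 exons). Small enough for second-scale tests,
  large enough for ~3,000 planted sites.
* Planting: density 0.01 per strand-specific dA outside clusters; feature
  bias (promoter 3, 5'UTR 3, exon 2, intron 1.5, intergenic 0.5) and AG/GA
  odds multiplier beta = 5 reproduce enrichment near TSS/exons, depletion
  intergenic, and a strong AG/GA preference.
* Fractions: spike of weight 0.15 at exactly 1.0 plus a Beta(2, 2) body — a
  visible homogeneous-methylation peak over a broad heterogeneous bulk.
* Haplotypes: 70% of non-cluster sites methylated on exactly one haplotype
  (diploid fraction = half the on-haplotype fraction under balanced
  coverage); 28% of molecules left unphased, matching a realistic phasing
  yield (~72%).
* Clusters: 8 regions of 500 bp with A/T probability 0.67, each holding
  16-22 sites in several tight runs (inter-site spacing a few bp);
  fractions 0.45 + 0.35*Beta(1.2, 3) — mostly callable yet systematically
  lower than isolated sites. With these settings clusters hold ~10-13% of
  called sites.
* Kinetics: coverage ~ Poisson(40) (clamped at 5), passes ~ 1 + Poisson(9);
  unmethylated spot-check positions at density 0.003 populate the null set.
  Haplotype analyses use coverage 100 so both haplotigs clear 20x, the
  regime of a deeply sequenced diploid line.
* Trio: 2,000 called sites per member drawn from a 50,000-position dA
  universe, a 600-site conserved pool (each member takes each with
  probability 0.25) creating above-chance unrelated overlap; the son
  inherits each parental site with probability 0.5 and fills with noise;
  failed-filter pools are 4x the call-set size.
* Expression: log TPM = 2 + 1.0 x [gene has 6mA] + Normal(0, 1); ASE genes
  (those with haplotype-restricted methylation, link probability 1.0) draw
  allele counts Binomial(100, 0.8) toward the methylated haplotype.

What the generator does **not** emulate — and hence what passing tests do
not establish about real data: sequence-context-dependent kinetic
signatures (the shift `delta` is context-free), alignment and mappability
artifacts in repetitive regions, polymerase error profiles, other
modifications (m5dC, m4dC), detection bias in the failed-filter null
(in real data the null set shares the motif-context detection bias, which
is why it is used as background; in the generator the planted bias itself
leaks into low-fraction failed sites, so motif-recovery experiments use
homogeneous methylation where the null reduces to clean background), and
base-composition confounding between AT-rich clusters and motif tests
(cluster contexts are AT-skewed; motif experiments therefore exclude
cluster regions).

## Problem sizes in tests and acceptance

Tests and the acceptance script run at desk scale by design: ~3,000
planted sites per simulation, 1,000-shuffle permutations where a p-value
floor matters (20-200 shuffles for smoke checks), 500 random layouts for
the cluster oracle, and 100-seed batteries for calibration/power
estimates (trio relatedness, motif and expression nulls). Published
genome-scale counts (tens of thousands of sites) are used only as
arithmetic inputs, never re-estimated.

## Known limitations

* The EM fraction estimator assumes the kinetic model that generated the
  data; model misspecification on real kinetics is not quantified here.
* Cluster detection counts strand-specific records toward the 10-site
  threshold; a strand-collapsed variant would be slightly stricter.
* The relatedness proportion test inherits the conservativeness described
  above; its permutation counterpart is exact by construction.
* The 4-mer motif combination implements one of two defensible readings of
  the combination procedure.
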