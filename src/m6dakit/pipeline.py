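"""End-to-end orchestration over a simulated (or on-disk) data bundle.

``run_pipeline`` runs the stages in dependency order - calling, annotation
enrichment, motifs, clusters, haplotypes, trio, expression - and writes
plain-text tables plus a manifest (input hashes, seed, version) sufficient
to reproduce every output.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass, field
from typing import Dict

import pandas as pd

from . import __version__
from . import io as mio
from .annotate import (
    assign_features,
    build_label_map,
    chromosome_m6dA_dA,
    feature_fold_enrichment,
)
from .calling import CallingParams, filter_sites
from .clusters import (
    cluster_abundance_pvalue,
    cluster_stats,
    clusters_to_bed,
    compare_cluster_vs_single,
    detect_clusters,
)
from .expression import ase_test, tpm_by_m6dA_status
from .haplotypes import (
    haplotype_exclusivity,
    regress_diploid_on_haplotypes,
    split_and_call_by_haplotype,
    trio_analysis,
)
from .motifs import (
    combine_motifs,
    dinucleotide_enrichment,
    motif_table,
    significant_dinucleotides,
)
from .stats import ShuffleUniverse

ALL_STAGES = ("call", "annotate", "motif", "clusters", "haplo", "trio", "expression")


@dataclass
class PipelineConfig:
    """Paths, thresholds and reproducibility settings for a full run."""

    bundle_dir: str
    out_dir: str
    params: CallingParams = field(default_factory=CallingParams)
    n_perm: int = 1000
    seed: int = 0
    stages: tuple = ALL_STAGES


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> Dict[str, object]:
    """Run the requested stages over a bundle directory; returns the result
    objects keyed by stage and writes tables plus ``manifest.json``."""
    b = config.bundle_dir
    os.makedirs(config.out_dir, exist_ok=True)
    genome = mio.read_genome(os.path.join(b, "genome.fa"))
    annotation = mio.read_annotation(os.path.join(b, "genes.gff3"))
    sites_all = mio.read_modifications(os.path.join(b, "kinetics.tsv"), dialect="tabular")

    results: Dict[str, object] = {}
    lm = build_label_map(annotation)
    universe = ShuffleUniverse.from_genome(genome)

    called, null_set = filter_sites(sites_all, config.params)
    if "call" in config.stages:
        mio.write_modifications(called, os.path.join(config.out_dir, "called.gff3"))
        mio.write_modifications(null_set, os.path.join(config.out_dir, "null_set.gff3"))
        results["call"] = {"n_called": len(called), "n_null": len(null_set)}

    assignments = assign_features(called, annotation, lm)
    feature_of = {a.site: a.feature for a in assignments}
    gene_of = {a.site: a.gene_id for a in assignments}

    if "annotate" in config.stages:
        chrom_tab = chromosome_m6dA_dA(called, genome)
        enrich = feature_fold_enrichment(
            called, annotation, genome,
            n_perm=config.n_perm, seed=config.seed, label_map=lm,
        )
        chrom_tab.to_csv(os.path.join(config.out_dir, "chrom_ratio.tsv"), sep="\t", index=False)
        enrich.to_csv(os.path.join(config.out_dir, "feature_enrichment.tsv"), sep="\t", index=False)
        results["annotate"] = {"chrom": chrom_tab, "enrichment": enrich}

    if "motif" in config.stages:
        fg = [s.context for s in called if s.context]
        nl = [s.context for s in null_set if s.context]
        dinuc = dinucleotide_enrichment(fg, nl)
        sig = significant_dinucleotides(dinuc)
        combined = combine_motifs(sig, fg, nl) if sig else []
        tab = motif_table(dinuc + list(combined))
        tab.to_csv(os.path.join(config.out_dir, "motifs.tsv"), sep="\t", index=False)
        results["motif"] = tab

    if "clusters" in config.stages:
        cl, singles = detect_clusters(called)
        stats_tab = cluster_stats(cl, genome)
        obs_frac, p = cluster_abundance_pvalue(
            called, universe, n_perm=config.n_perm, seed=config.seed
        )
        bed = clusters_to_bed(cl)
        bed.to_csv(os.path.join(config.out_dir, "clusters.bed"), sep="\t", index=False, header=False)
        comparison = (
            compare_cluster_vs_single(
                called.subset([k for c in cl for k in c.members]), singles, feature_of
            )
            if cl and len(singles)
            else None
        )
        results["clusters"] = {
            "clusters": cl,
            "stats": stats_tab,
            "clustered_fraction": obs_frac,
            "pvalue": p,
            "comparison": comparison,
        }

    hap_calls = None
    if "haplo" in config.stages:
        molecules = mio.read_molecules(os.path.join(b, "molecules.tsv"))
        hap_calls = split_and_call_by_haplotype(molecules, config.params)
        excl = haplotype_exclusivity(hap_calls.hp1_called, hap_calls.hp2_called)
        regression = regress_diploid_on_haplotypes(hap_calls.table)
        hap_calls.table.to_csv(
            os.path.join(config.out_dir, "haplotype_table.tsv"), sep="\t", index=False
        )
        regression.to_csv(
            os.path.join(config.out_dir, "haplotype_regression.tsv"), sep="\t", index=False
        )
        results["haplo"] = {
            "calls": hap_calls,
            "exclusivity": excl,
            "regression": regression,
        }

    if "trio" in config.stages:
        sites = {
            n: mio.read_modifications(os.path.join(b, f"trio_{n}.tsv"), dialect="tabular")
            for n in ("mother", "father", "son")
        }
        pools = {
            n: mio.read_modifications(os.path.join(b, f"trio_{n}_pool.tsv"), dialect="tabular")
            for n in ("mother", "father", "son")
        }
        trio = trio_analysis(sites, pools, n_perm=config.n_perm, seed=config.seed)
        trio.relatedness.to_csv(
            os.path.join(config.out_dir, "trio_relatedness.tsv"), sep="\t", index=False
        )
        results["trio"] = trio

    if "expression" in config.stages:
        expr = mio.read_expression(os.path.join(b, "expression.tsv"))
        genes_with = {g for g in gene_of.values() if g is not None}
        try:
            tpm = tpm_by_m6dA_status(expr, genes_with, feature="gene")
        except ValueError:
            tpm = None  # degenerate split: every (or no) gene carries 6mA
        ase = ase_test(expr)
        ase.to_csv(os.path.join(config.out_dir, "ase.tsv"), sep="\t", index=False)
        results["expression"] = {"tpm": tpm, "ase": ase}

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "n_perm": config.n_perm,
        "params": dataclasses.asdict(config.params),
        "stages": list(config.stages),
        "inputs": {
            f: _sha256(os.path.join(b, f))
            for f in sorted(os.listdir(b))
            if os.path.isfile(os.path.join(b, f))
        },
    }
    with open(os.path.join(config.out_dir, "manifest.json"), "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1)
    results["manifest"] = manifest
    return results
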