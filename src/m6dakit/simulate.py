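"""Ground-truthed synthetic data with the statistical structure the
analysis assumes.

The generator emits a toy genome (3 chromosomes of 200 kb), a non-overlapping
gene annotation, per-molecule log-normal IPD kinetics with a methylation-
dependent shift, AT-rich dense-site clusters, AG/GA motif bias, feature-
biased site placement, SNP-phased haplotypes with haplotype-restricted
methylation, a trio with tunable inheritance, and gene expression positively
coupled to genic 6mA including allele-specific expression. Every stage draws
from an independent named substream of one shared integer seed, so adding a
stage never perturbs earlier draws.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from . import io as mio
from .annotate import build_label_map
from .calling import CallingParams, call_from_molecules
from .types import (
    GenomeAnnotation,
    KineticSite,
    MoleculeObservation,
    SiteSet,
    Transcript,
)

_COMP = str.maketrans("ACGTN", "TGCAN")

# Stable substream ids; append only.
_STAGES = {
    "genome": 1,
    "genes": 2,
    "plant": 3,
    "kinetics": 4,
    "snps": 5,
    "trio": 6,
    "expression": 7,
}


def _rng(seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), _STAGES[stage]]))


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass
class SimulationConfig:
    """All knobs of the generator, with defaults matching the study design
    the pipeline assumes (see docs/methods.md for rationale)."""

    seed: int = 0
    chrom_sizes: Dict[str, int] = field(
        default_factory=lambda: {"chr1": 200_000, "chr2": 200_000, "chr3": 200_000}
    )
    # gene structure
    n_genes: int = 30
    exon_range: Tuple[int, int] = (2, 5)
    exon_len_range: Tuple[int, int] = (150, 450)
    intron_len_range: Tuple[int, int] = (300, 800)
    utr_len: int = 100
    gene_gap_range: Tuple[int, int] = (2000, 6000)
    # site planting
    m6dA_density: float = 0.01  # per strand-specific dA, outside clusters
    spike_weight: float = 0.15  # mass at fraction exactly 1.0
    beta_a: float = 2.0
    beta_b: float = 2.0
    motif_bias: float = 5.0  # odds multiplier for AG/GA neighbor contexts
    feature_bias: Dict[str, float] = field(
        default_factory=lambda: {
            "promoter": 3.0,
            "utr5": 3.0,
            "utr3": 1.0,
            "exon": 2.0,
            "intron": 1.5,
            "downstream": 1.0,
            "intergenic": 0.5,
        }
    )
    # clusters
    n_clusters: int = 8
    cluster_size: int = 500
    cluster_sites_range: Tuple[int, int] = (16, 22)
    cluster_runs: int = 4  # tight site runs spread across each region
    cluster_at: float = 0.67
    # cluster fractions: base + scale * Beta(a, b) - mostly callable but
    # systematically lower than isolated sites
    cluster_frac_base: float = 0.45
    cluster_frac_scale: float = 0.35
    cluster_frac_a: float = 1.2
    cluster_frac_b: float = 3.0
    # kinetics
    coverage_mean: float = 40.0
    coverage_min: int = 5
    mu0: float = 0.0
    sigma: float = 0.5
    delta: float = float(np.log(16.0))
    n_passes_mean: float = 10.0
    spot_check_density: float = 0.003  # unmethylated dA emitted for the null set
    # haplotypes
    snp_rate: float = 0.002
    untag_rate: float = 0.28  # share of molecules left unphased
    hap_restricted_prop: float = 0.7
    # trio
    trio_n_sites: int = 2000
    trio_universe: int = 50_000
    trio_pool_factor: int = 4
    inheritance_p: float = 0.5
    common_pool_size: int = 600
    common_take_p: float = 0.25
    # expression
    expr_baseline: float = 2.0  # log TPM
    expr_effect: float = 1.0
    expr_noise_sd: float = 1.0
    ase_depth: int = 100
    ase_bias: float = 0.8
    ase_link: float = 1.0

    def __post_init__(self) -> None:
        for name in ("spike_weight", "hap_restricted_prop", "inheritance_p",
                     "untag_rate", "common_take_p", "ase_bias", "ase_link"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if np.exp(self.delta) < 1.0:
            raise ValueError("delta must be a positive log-IPD shift")


@dataclass
class GroundTruth:
    """Planted truth sufficient to score every downstream stage."""

    sites: pd.DataFrame  # chrom,pos,strand,fraction,hap_fraction,hap,in_cluster,has_ag_ga
    cluster_regions: Dict[str, List[Tuple[int, int]]]
    genes: pd.DataFrame  # gene_id,has_m6dA,diff_meth_hap,is_ase
    config: SimulationConfig

    def save(self, outdir: str) -> None:
        os.makedirs(outdir, exist_ok=True)
        self.sites.to_csv(os.path.join(outdir, "truth_sites.tsv"), sep="\t", index=False)
        self.genes.to_csv(os.path.join(outdir, "truth_genes.tsv"), sep="\t", index=False)
        mio.write_regions(self.cluster_regions, os.path.join(outdir, "truth_clusters.bed"))
        with open(os.path.join(outdir, "config.json"), "w", encoding="utf-8") as fh:
            json.dump(dataclasses.asdict(self.config), fh, indent=1, default=list)


# ---------------------------------------------------------------------------
# Genome and annotation
# ---------------------------------------------------------------------------

def generate_genome(
    config: SimulationConfig,
) -> Tuple[Dict[str, str], GenomeAnnotation, Dict[str, List[Tuple[int, int]]]]:
    """Simulate the genome sequence, gene annotation and cluster regions.

    Base composition is uniform (A/T probability 0.5 overall) except inside
    designated cluster regions, where the A/T probability is raised to
    ``cluster_at``. Genes are packed left to right with random gaps and never
    overlap; a packing that cannot fit ``n_genes`` raises.
    """
    rng = _rng(config.seed, "genome")
    chroms = sorted(config.chrom_sizes)

    # Cluster regions: round-robin across chromosomes, sampled left to right.
    cluster_regions: Dict[str, List[Tuple[int, int]]] = {c: [] for c in chroms}
    per_chrom = np.zeros(len(chroms), dtype=int)
    for i in range(config.n_clusters):
        per_chrom[i % len(chroms)] += 1
    for ci, chrom in enumerate(chroms):
        size = config.chrom_sizes[chrom]
        k = per_chrom[ci]
        if k == 0:
            continue
        # k non-overlapping windows, uniformly spread with jitter
        slot = size // (k + 1)
        for j in range(k):
            base = (j + 1) * slot
            start = int(base + rng.integers(-slot // 4, slot // 4))
            start = min(max(100, start), size - config.cluster_size - 100)
            cluster_regions[chrom].append((start, start + config.cluster_size))
        cluster_regions[chrom].sort()

    genome: Dict[str, str] = {}
    base_probs = np.array([0.25, 0.25, 0.25, 0.25])
    at = config.cluster_at
    cluster_probs = np.array([at / 2, (1 - at) / 2, (1 - at) / 2, at / 2])
    alphabet = np.frombuffer(b"ACGT", dtype=np.uint8)
    for chrom in chroms:
        size = config.chrom_sizes[chrom]
        draw = rng.choice(4, size=size, p=base_probs)
        for a, b in cluster_regions[chrom]:
            draw[a:b] = rng.choice(4, size=b - a, p=cluster_probs)
        genome[chrom] = alphabet[draw].tobytes().decode("ascii")

    annotation = _generate_genes(config, chroms)
    return genome, annotation, cluster_regions


def _generate_genes(config: SimulationConfig, chroms: List[str]) -> GenomeAnnotation:
    rng = _rng(config.seed, "genes")
    transcripts: List[Transcript] = []
    per_chrom = np.zeros(len(chroms), dtype=int)
    for i in range(config.n_genes):
        per_chrom[i % len(chroms)] += 1
    gi = 0
    for ci, chrom in enumerate(chroms):
        size = config.chrom_sizes[chrom]
        cursor = 2000
        for _ in range(per_chrom[ci]):
            cursor += int(rng.integers(*config.gene_gap_range))
            n_exons = int(rng.integers(config.exon_range[0], config.exon_range[1] + 1))
            exons: List[Tuple[int, int]] = []
            p = cursor
            for e in range(n_exons):
                if e > 0:
                    p += int(rng.integers(*config.intron_len_range))
                elen = int(rng.integers(*config.exon_len_range))
                exons.append((p, p + elen))
                p += elen
            if p > size - 2000:
                raise ValueError(
                    f"cannot pack {config.n_genes} genes into the configured genome"
                )
            strand = "+" if rng.random() < 0.5 else "-"
            gid = f"g{gi:03d}"
            gi += 1
            u = config.utr_len
            first, last = exons[0], exons[-1]
            if strand == "+":
                utr5 = ((first[0], min(first[0] + u, first[1])),)
                utr3 = ((max(last[1] - u, last[0]), last[1]),)
            else:
                utr5 = ((max(last[1] - u, last[0]), last[1]),)
                utr3 = ((first[0], min(first[0] + u, first[1])),)
            transcripts.append(
                Transcript(
                    gene_id=gid,
                    chrom=chrom,
                    strand=strand,
                    start=exons[0][0],
                    end=exons[-1][1],
                    exons=tuple(exons),
                    utr5=utr5,
                    utr3=utr3,
                )
            )
            cursor = p
    return GenomeAnnotation(transcripts=transcripts, chrom_sizes=dict(config.chrom_sizes))


# ---------------------------------------------------------------------------
# Site planting
# ---------------------------------------------------------------------------

def _strand_arrays(seq: str) -> Dict[str, np.ndarray]:
    """Positions of adenosines per strand (ref A = '+', ref T = '-')."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return {
        "+": np.nonzero(arr == ord("A"))[0],
        "-": np.nonzero(arr == ord("T"))[0],
    }


def _has_g_neighbor(seq_arr: np.ndarray, pos: np.ndarray, strand: str) -> np.ndarray:
    """AG/GA membership: is the immediate up- or downstream neighbor on the
    site's strand a G?"""
    left = np.where(pos > 0, seq_arr[np.maximum(pos - 1, 0)], 0)
    right = np.where(pos < len(seq_arr) - 1, seq_arr[np.minimum(pos + 1, len(seq_arr) - 1)], 0)
    if strand == "+":
        return (left == ord("G")) | (right == ord("G"))
    # minus strand: neighbors are the complements of the flanking ref bases
    return (left == ord("C")) | (right == ord("C"))


def plant_m6dA(
    genome: Dict[str, str],
    annotation: GenomeAnnotation,
    config: SimulationConfig,
    cluster_regions: Dict[str, List[Tuple[int, int]]],
) -> pd.DataFrame:
    """Choose true methylated adenosines and their fractions.

    Placement odds are multiplied by the feature bias of the position's label
    and by ``motif_bias`` when the immediate strand-specific neighbor is a G
    (AG/GA context). Fractions are a spike at 1.0 (weight ``spike_weight``)
    plus a Beta body; cluster regions get a dense run of closely spaced,
    haplotype-unrestricted sites whose fractions sit above the detection
    range but below the homogeneous spike (dense regions carry consistently
    lower methylated fractions than isolated sites). A share
    ``hap_restricted_prop`` of non-cluster sites is methylated on exactly
    one haplotype: for those the diploid ``fraction`` is half the
    on-haplotype ``hap_fraction`` (balanced haplotype coverage).
    """
    rng = _rng(config.seed, "plant")
    lm = build_label_map(annotation)
    margin = 20  # keep full 41-mer contexts on-chromosome
    rows: List[dict] = []
    from .types import FEATURE_LABELS

    bias_by_code = np.array(
        [config.feature_bias.get(f, 1.0) for f in FEATURE_LABELS], dtype=float
    )

    for chrom in sorted(genome):
        seq = genome[chrom]
        seq_arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        labels = lm.labels[chrom]
        in_cluster = np.zeros(len(seq), dtype=bool)
        for a, b in cluster_regions.get(chrom, []):
            in_cluster[a:b] = True
        strands = _strand_arrays(seq)
        for strand in ("+", "-"):
            pos = strands[strand]
            pos = pos[(pos >= margin) & (pos < len(seq) - margin)]
            motif = _has_g_neighbor(seq_arr, pos, strand)
            outside = ~in_cluster[pos]
            cand = pos[outside]
            cand_motif = motif[outside]
            w = bias_by_code[labels[cand]] * np.where(cand_motif, config.motif_bias, 1.0)
            n_plant = int(round(config.m6dA_density * len(cand)))
            if n_plant > len(cand):
                raise ValueError("m6dA density too high for available adenosines")
            # weighted sampling without replacement (Efraimidis-Spirakis keys)
            keys = rng.random(len(cand)) ** (1.0 / w)
            take = np.argsort(keys)[-n_plant:]
            for i in np.sort(take):
                rows.append(
                    {
                        "chrom": chrom,
                        "pos": int(cand[i]),
                        "strand": strand,
                        "in_cluster": False,
                        "has_ag_ga": bool(cand_motif[i]),
                    }
                )
        # cluster sites: several tight runs of dA positions (strands pooled)
        # spread across each region, so spans cover the AT-rich sequence
        # while successive inter-site distances stay a few bp
        for a, b in cluster_regions.get(chrom, []):
            n_c = int(rng.integers(*config.cluster_sites_range))
            both = np.sort(np.concatenate([strands["+"], strands["-"]]))
            inside = both[(both >= max(a, margin)) & (both < min(b, len(seq) - margin))]
            k_runs = max(1, config.cluster_runs)
            per_run = -(-n_c // k_runs)  # ceil
            stride = int(rng.integers(2, 4))
            picked_list = []
            for r_i in range(k_runs):
                seg_lo = a + r_i * (b - a) // k_runs
                seg = inside[inside >= seg_lo]
                picked_list.append(seg[::stride][:per_run])
            picked = np.unique(np.concatenate(picked_list))[:n_c]
            if len(picked) < 10:
                picked = inside[:n_c]
            plus = set(strands["+"])
            for p in picked:
                strand = "+" if int(p) in plus else "-"
                motif = bool(
                    _has_g_neighbor(seq_arr, np.array([int(p)]), strand)[0]
                )
                rows.append(
                    {
                        "chrom": chrom,
                        "pos": int(p),
                        "strand": strand,
                        "in_cluster": True,
                        "has_ag_ga": motif,
                    }
                )

    df = pd.DataFrame(rows).drop_duplicates(["chrom", "pos", "strand"])
    n = len(df)
    # on-haplotype fractions: spike at 1.0 plus a Beta body
    spike = rng.random(n) < config.spike_weight
    hap_fraction = np.where(
        spike, 1.0, rng.beta(config.beta_a, config.beta_b, size=n)
    )
    clus = df["in_cluster"].to_numpy()
    hap_fraction = np.where(
        clus,
        config.cluster_frac_base
        + config.cluster_frac_scale
        * rng.beta(config.cluster_frac_a, config.cluster_frac_b, size=n),
        hap_fraction,
    )
    restricted = (rng.random(n) < config.hap_restricted_prop) & ~clus
    hap = np.where(restricted, rng.integers(1, 3, size=n), 0)
    fraction = np.where(restricted, hap_fraction / 2.0, hap_fraction)
    df = df.assign(hap_fraction=hap_fraction, hap=hap, fraction=fraction)
    df = df.sort_values(["chrom", "pos", "strand"]).reset_index(drop=True)
    return df


# ---------------------------------------------------------------------------
# Kinetics
# ---------------------------------------------------------------------------

def context_of(genome: Dict[str, str], chrom: str, pos: int, strand: str) -> Optional[str]:
    seq = genome[chrom]
    if pos < 20 or pos + 21 > len(seq):
        return None
    window = seq[pos - 20 : pos + 21]
    return window if strand == "+" else revcomp(window)


def simulate_kinetics(
    true_sites: pd.DataFrame,
    genome: Dict[str, str],
    config: SimulationConfig,
) -> Tuple[List[MoleculeObservation], SiteSet]:
    """Emit per-molecule IPD observations and per-site kinetic summaries.

    Each molecule at a site is first assigned a haplotype (1 or 2, balanced)
    and a phasing tag (observed with probability 1 - untag_rate). It is
    methylated with probability ``hap_fraction`` when the site is unrestricted
    or when its haplotype matches the site's methylated haplotype, otherwise
    never. Mean log IPD per molecule is Normal(mu0 + delta*methylated,
    sigma^2 / n_passes). Unmethylated genome positions are also emitted at
    ``spot_check_density``; their records populate the failed-filter null
    set downstream. Site summaries (coverage, IPD ratio, EM fraction,
    context) are produced by the calling layer from the simulated molecules.
    """
    rng = _rng(config.seed, "kinetics")
    molecules: List[MoleculeObservation] = []
    contexts: Dict[Tuple[str, int, str], str] = {}
    mol_id = 0

    planted = set()
    site_rows = list(true_sites.itertuples(index=False))
    for r in site_rows:
        planted.add((r.chrom, int(r.pos), r.strand))

    # spot-check unmethylated positions
    spot_rows = []
    for chrom in sorted(genome):
        strands = _strand_arrays(genome[chrom])
        for strand in ("+", "-"):
            pos = strands[strand]
            pos = pos[(pos >= 20) & (pos < len(genome[chrom]) - 20)]
            n_spot = int(round(config.spot_check_density * len(pos)))
            take = rng.choice(len(pos), size=n_spot, replace=False)
            for p in np.sort(pos[take]):
                key = (chrom, int(p), strand)
                if key not in planted:
                    spot_rows.append(key)

    def emit(chrom: str, pos: int, strand: str, hap_fraction: float, hap: int) -> None:
        nonlocal mol_id
        cov = max(config.coverage_min, int(rng.poisson(config.coverage_mean)))
        npass = 1 + rng.poisson(config.n_passes_mean - 1.0, size=cov)
        mol_hap = rng.integers(1, 3, size=cov)
        tagged = rng.random(cov) >= config.untag_rate
        if hap == 0:
            meth = rng.random(cov) < hap_fraction
        else:
            meth = (mol_hap == hap) & (rng.random(cov) < hap_fraction)
        mli = rng.normal(
            config.mu0 + config.delta * meth, config.sigma / np.sqrt(npass)
        )
        for k in range(cov):
            molecules.append(
                MoleculeObservation(
                    chrom=chrom,
                    pos=pos,
                    strand=strand,
                    molecule_id=mol_id,
                    mean_log_ipd=float(mli[k]),
                    n_passes=int(npass[k]),
                    haplotype_tag=f"HP{mol_hap[k]}" if tagged[k] else "untagged",
                )
            )
            mol_id += 1
        ctx = context_of(genome, chrom, pos, strand)
        if ctx is not None:
            contexts[(chrom, pos, strand)] = ctx

    for r in site_rows:
        emit(r.chrom, int(r.pos), r.strand, float(r.hap_fraction), int(r.hap))
    for chrom, pos, strand in spot_rows:
        emit(chrom, pos, strand, 0.0, 0)

    params = CallingParams(mu0=config.mu0, sigma=config.sigma, delta=config.delta)
    summaries = call_from_molecules(molecules, params, contexts)
    return molecules, summaries


# ---------------------------------------------------------------------------
# Haplotypes (phased SNPs) and trio
# ---------------------------------------------------------------------------

def simulate_phased_snps(genome: Dict[str, str], config: SimulationConfig) -> pd.DataFrame:
    """Heterozygous phased SNPs at ``snp_rate`` per base (the phasing
    information that makes haplotype tags possible)."""
    if config.snp_rate <= 0:
        raise ValueError("snp_rate must be > 0 when haplotyping is requested")
    rng = _rng(config.seed, "snps")
    rows = []
    bases = "ACGT"
    for chrom in sorted(genome):
        seq = genome[chrom]
        n = rng.binomial(len(seq), config.snp_rate)
        pos = np.sort(rng.choice(len(seq), size=n, replace=False))
        for p in pos:
            ref = seq[p]
            alt = bases[int(rng.integers(0, 4))]
            while alt == ref:
                alt = bases[int(rng.integers(0, 4))]
            alt_on_hp1 = bool(rng.random() < 0.5)
            rows.append(
                {
                    "chrom": chrom,
                    "pos": int(p),
                    "ref": ref,
                    "alt": alt,
                    "hp1": alt if alt_on_hp1 else ref,
                    "hp2": ref if alt_on_hp1 else alt,
                }
            )
    return pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "hp1", "hp2"])


@dataclass
class TrioData:
    """Called site sets and failed-filter pools for mother, father, son."""

    sites: Dict[str, SiteSet]
    pools: Dict[str, SiteSet]
    inherited_from: pd.DataFrame  # son site -> parent of origin (ground truth)


def simulate_trio(genome: Dict[str, str], config: SimulationConfig) -> TrioData:
    """Three individuals' site tables with tunable inheritance.

    Parents draw sites independently from the dA universe plus a small
    shared "conserved" pool (so unrelated overlap sits above chance); the son
    inherits each parental site with probability ``inheritance_p`` and fills
    up with independent noise sites. Failed-filter pools (coverage 11-19 or
    IPD ratio < 4) are drawn per individual for the permutation null.
    """
    rng = _rng(config.seed, "trio")
    # flatten a universe subsample of (chrom,pos,strand)
    keys: List[Tuple[str, int, str]] = []
    for chrom in sorted(genome):
        strands = _strand_arrays(genome[chrom])
        for strand in ("+", "-"):
            for p in strands[strand]:
                keys.append((chrom, int(p), strand))
    keys_idx = rng.choice(len(keys), size=min(config.trio_universe, len(keys)), replace=False)
    U = [keys[i] for i in np.sort(keys_idx)]
    n_u = len(U)
    common_idx = rng.choice(n_u, size=config.common_pool_size, replace=False)
    common = set(common_idx.tolist())

    def draw_individual() -> set:
        taken = {i for i in common if rng.random() < config.common_take_p}
        need = config.trio_n_sites - len(taken)
        rest = rng.choice(n_u, size=min(3 * config.trio_n_sites, n_u), replace=False)
        for i in rest:
            if need == 0:
                break
            if i not in taken:
                taken.add(int(i))
                need -= 1
        return taken

    mother = draw_individual()
    father = draw_individual()
    inherited_rows = []
    son: set = set()
    for parent_name, parent in (("mother", mother), ("father", father)):
        for i in parent:
            if rng.random() < config.inheritance_p:
                son.add(i)
                inherited_rows.append({"index": i, "parent": parent_name})
    if len(son) < config.trio_n_sites:
        need = config.trio_n_sites - len(son)
        taken = {i for i in common if rng.random() < config.common_take_p}
        son |= taken
        need = max(0, config.trio_n_sites - len(son))
        rest = rng.choice(n_u, size=min(3 * config.trio_n_sites, n_u), replace=False)
        for i in rest:
            if need == 0:
                break
            if i not in son:
                son.add(int(i))
                need -= 1

    def make_sites(index_set: set, called: bool) -> SiteSet:
        out = []
        for i in sorted(index_set):
            chrom, pos, strand = U[i]
            if called:
                cov = 20 + int(rng.poisson(20))
                ratio = float(4.0 + rng.gamma(2.0, 2.0))
                frac = float(rng.uniform(0.5, 1.0))
            else:
                cov = int(rng.integers(11, 20))
                ratio = float(rng.uniform(1.0, 3.5))
                frac = float(rng.uniform(0.0, 0.4))
            out.append(
                KineticSite(
                    chrom=chrom, pos=pos, strand=strand,
                    coverage=cov, ipd_ratio=ratio, meth_fraction=frac,
                )
            )
        return SiteSet(out)

    sites = {}
    pools = {}
    for name, idx in (("mother", mother), ("father", father), ("son", son)):
        sites[name] = make_sites(idx, called=True)
        pool_n = min(config.trio_pool_factor * config.trio_n_sites, n_u - len(idx))
        avail = np.array(sorted(set(range(n_u)) - idx))
        pool_idx = set(avail[rng.choice(len(avail), size=pool_n, replace=False)].tolist())
        pools[name] = make_sites(pool_idx, called=False)
    return TrioData(
        sites=sites,
        pools=pools,
        inherited_from=pd.DataFrame(inherited_rows, columns=["index", "parent"]),
    )


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------

def simulate_expression(
    config: SimulationConfig,
    gene_ids: List[str],
    genes_with_m6dA: set,
    diff_meth_hap: Dict[str, int],
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Gene TPM and phased allele counts coupled to 6mA status.

    log TPM = baseline + effect * 1[gene has 6mA] + Normal(0, noise_sd).
    Genes with haplotype-restricted methylation become allele-specific
    expressers with probability ``ase_link``; their allele counts are
    binomial with success probability ``ase_bias`` toward the methylated
    haplotype, all other genes are balanced at 0.5.
    """
    rng = _rng(config.seed, "expression")
    rows = []
    truth = []
    for gid in gene_ids:
        has = gid in genes_with_m6dA
        log_tpm = (
            config.expr_baseline
            + config.expr_effect * has
            + rng.normal(0.0, config.expr_noise_sd)
        )
        hap = diff_meth_hap.get(gid, 0)
        is_ase = hap != 0 and rng.random() < config.ase_link
        if is_ase:
            p1 = config.ase_bias if hap == 1 else 1.0 - config.ase_bias
        else:
            p1 = 0.5
        h1 = int(rng.binomial(config.ase_depth, p1))
        rows.append(
            {
                "gene_id": gid,
                "tpm": float(np.exp(log_tpm)),
                "hap1_count": h1,
                "hap2_count": config.ase_depth - h1,
            }
        )
        truth.append(
            {"gene_id": gid, "has_m6dA": has, "diff_meth_hap": hap, "is_ase": is_ase}
        )
    return pd.DataFrame(rows), pd.DataFrame(truth)


# ---------------------------------------------------------------------------
# Bundle
# ---------------------------------------------------------------------------

@dataclass
class SimulatedBundle:
    config: SimulationConfig
    genome: Dict[str, str]
    annotation: GenomeAnnotation
    truth: GroundTruth
    molecules: List[MoleculeObservation]
    site_summaries: SiteSet
    phased_snps: pd.DataFrame
    trio: TrioData
    expression: pd.DataFrame

    def save(self, outdir: str) -> None:
        os.makedirs(outdir, exist_ok=True)
        mio.write_genome(self.genome, os.path.join(outdir, "genome.fa"))
        mio.write_annotation(self.annotation, os.path.join(outdir, "genes.gff3"))
        mio.write_modifications(
            self.site_summaries, os.path.join(outdir, "kinetics.tsv"), dialect="tabular"
        )
        mio.write_molecules(self.molecules, os.path.join(outdir, "molecules.tsv"))
        mio.write_phased_snps(self.phased_snps, os.path.join(outdir, "phased_snps.tsv"))
        mio.write_expression(self.expression, os.path.join(outdir, "expression.tsv"))
        for name in ("mother", "father", "son"):
            mio.write_modifications(
                self.trio.sites[name],
                os.path.join(outdir, f"trio_{name}.tsv"),
                dialect="tabular",
            )
            mio.write_modifications(
                self.trio.pools[name],
                os.path.join(outdir, f"trio_{name}_pool.tsv"),
                dialect="tabular",
            )
        self.truth.save(outdir)


def simulate_bundle(config: SimulationConfig, outdir: Optional[str] = None) -> SimulatedBundle:
    """Run every generator stage and (optionally) write the file bundle."""
    genome, annotation, cluster_regions = generate_genome(config)
    true_sites = plant_m6dA(genome, annotation, config, cluster_regions)
    molecules, summaries = simulate_kinetics(true_sites, genome, config)
    snps = simulate_phased_snps(genome, config)
    trio = simulate_trio(genome, config)

    lm = build_label_map(annotation)
    genes_with = set()
    diff_hap: Dict[str, int] = {}
    for r in true_sites.itertuples(index=False):
        gid = lm.gene_at(r.chrom, int(r.pos))
        if gid is None:
            continue
        genes_with.add(gid)
        if int(r.hap) != 0 and gid not in diff_hap:
            diff_hap[gid] = int(r.hap)
    expression, gene_truth = simulate_expression(
        config, annotation.gene_ids, genes_with, diff_hap
    )

    truth = GroundTruth(
        sites=true_sites,
        cluster_regions=cluster_regions,
        genes=gene_truth,
        config=config,
    )
    bundle = SimulatedBundle(
        config=config,
        genome=genome,
        annotation=annotation,
        truth=truth,
        molecules=molecules,
        site_summaries=summaries,
        phased_snps=snps,
        trio=trio,
        expression=expression,
    )
    if outdir is not None:
        bundle.save(outdir)
    return bundle
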