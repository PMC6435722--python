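"""Feature assignment and m6dA/dA enrichment statistics.

Each genomic position gets exactly one feature label under the precedence
promoter > 5'UTR > 3'UTR > exon > intron > downstream (<= 1 kb past the
transcript end) > intergenic, with ties within one class resolved toward the
lowest gene id. Labels are materialised as per-chromosome arrays so that
per-feature dA denominators (strand-specific adenosine counts) and
permutation shuffles are O(1) lookups.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .stats import empirical_pvalue
from .types import FEATURE_LABELS, GenomeAnnotation, SiteKey, SiteSet

_LABEL_CODE = {name: i for i, name in enumerate(FEATURE_LABELS)}
_INTERGENIC = _LABEL_CODE["intergenic"]


@dataclass(frozen=True)
class FeatureAssignment:
    site: SiteKey
    feature: str
    gene_id: Optional[str]


@dataclass
class LabelMap:
    """Per-chromosome feature-label and gene-index arrays."""

    labels: Dict[str, np.ndarray]  # uint8 codes into FEATURE_LABELS
    gene_index: Dict[str, np.ndarray]  # int32 index into gene_ids, -1 = none
    gene_ids: List[str]

    def label_at(self, chrom: str, pos: int) -> str:
        return FEATURE_LABELS[self.labels[chrom][pos]]

    def gene_at(self, chrom: str, pos: int) -> Optional[str]:
        i = self.gene_index[chrom][pos]
        return None if i < 0 else self.gene_ids[i]


def build_label_map(annotation: GenomeAnnotation) -> LabelMap:
    """Paint feature labels chromosome-wide under the precedence rule."""
    gene_ids = annotation.gene_ids
    gene_pos = {g: i for i, g in enumerate(gene_ids)}
    labels = {
        c: np.full(n, _INTERGENIC, dtype=np.uint8)
        for c, n in annotation.chrom_sizes.items()
    }
    gidx = {
        c: np.full(n, -1, dtype=np.int32) for c, n in annotation.chrom_sizes.items()
    }

    def paint(chrom: str, iv: Tuple[int, int], code: int, gi: int) -> None:
        a = max(0, iv[0])
        b = min(len(labels[chrom]), iv[1])
        if a < b:
            labels[chrom][a:b] = code
            gidx[chrom][a:b] = gi

    # Lowest precedence first; later writes win. Within one class, descending
    # gene id so the lowest gene id is written last and takes ties.
    for feature in reversed(FEATURE_LABELS[:-1]):
        code = _LABEL_CODE[feature]
        for t in sorted(annotation.transcripts, key=lambda t: t.gene_id, reverse=True):
            gi = gene_pos[t.gene_id]
            if feature == "promoter":
                paint(t.chrom, t.promoter(annotation.promoter_upstream), code, gi)
            elif feature == "utr5":
                for iv in t.utr5:
                    paint(t.chrom, iv, code, gi)
            elif feature == "utr3":
                for iv in t.utr3:
                    paint(t.chrom, iv, code, gi)
            elif feature == "exon":
                for iv in t.exons:
                    paint(t.chrom, iv, code, gi)
            elif feature == "intron":
                for iv in t.introns():
                    paint(t.chrom, iv, code, gi)
            elif feature == "downstream":
                paint(t.chrom, t.downstream(annotation.downstream_length), code, gi)
    return LabelMap(labels=labels, gene_index=gidx, gene_ids=gene_ids)


def assign_features(
    sites: SiteSet,
    annotation: GenomeAnnotation,
    label_map: Optional[LabelMap] = None,
) -> List[FeatureAssignment]:
    """Assign exactly one feature label (and gene, where genic) per site."""
    lm = label_map or build_label_map(annotation)
    out: List[FeatureAssignment] = []
    for s in sites:
        if s.chrom not in lm.labels:
            raise ValueError(f"site on unknown chromosome {s.chrom}")
        if not 0 <= s.pos < len(lm.labels[s.chrom]):
            raise ValueError(f"site {s.key} beyond chromosome bounds")
        out.append(
            FeatureAssignment(
                site=s.key,
                feature=lm.label_at(s.chrom, s.pos),
                gene_id=lm.gene_at(s.chrom, s.pos),
            )
        )
    return out


def genes_with_sites(assignments: List[FeatureAssignment]) -> Dict[str, set]:
    """Per-feature sets of genes carrying at least one called site."""
    out: Dict[str, set] = {}
    for a in assignments:
        if a.gene_id is not None:
            out.setdefault(a.feature, set()).add(a.gene_id)
    return out


# ---------------------------------------------------------------------------
# dA denominators
# ---------------------------------------------------------------------------

def _dA_mask(seq: str, strand_specific: bool = True) -> np.ndarray:
    """Positions carrying an assayable adenosine (ref A = plus strand, ref T =
    minus strand). Each such position is one strand-specific site."""
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    if strand_specific:
        return (arr == ord("A")) | (arr == ord("T"))
    return arr == ord("A")


def chromosome_m6dA_dA(
    sites: SiteSet,
    genome: Dict[str, str],
    strand_specific: bool = True,
    exclude: Optional[Dict[str, List[Tuple[int, int]]]] = None,
) -> pd.DataFrame:
    """Per-chromosome m6dA / dA percentage (both strands pooled)."""
    rows = []
    counts: Dict[str, int] = {c: 0 for c in genome}
    for s in sites:
        if s.chrom not in genome:
            raise ValueError(f"chromosome {s.chrom} absent from genome")
        counts[s.chrom] += 1
    for chrom in sorted(genome):
        mask = _dA_mask(genome[chrom], strand_specific)
        if exclude and chrom in exclude:
            for a, b in exclude[chrom]:
                mask[max(0, a):min(len(mask), b)] = False
        n_dA = int(mask.sum())
        n_sites = counts[chrom]
        rows.append(
            {
                "chrom": chrom,
                "n_m6dA": n_sites,
                "n_dA": n_dA,
                "pct_m6dA_dA": 100.0 * n_sites / n_dA if n_dA else np.nan,
            }
        )
    return pd.DataFrame(rows)


def bin_profile(
    sites: SiteSet,
    genome: Dict[str, str],
    n_bins: int = 200,
    strand_specific: bool = True,
) -> Dict[str, pd.DataFrame]:
    """Split each chromosome into ``n_bins`` equal bins (last absorbs the
    remainder) and report the m6dA/dA percentage per bin."""
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    out: Dict[str, pd.DataFrame] = {}
    for chrom in sorted(genome):
        length = len(genome[chrom])
        if n_bins > length:
            raise ValueError(f"n_bins {n_bins} exceeds length of {chrom}")
        width = length // n_bins
        starts = np.arange(n_bins) * width
        ends = np.append(starts[1:], length)
        mask = _dA_mask(genome[chrom], strand_specific)
        cum = np.concatenate([[0], np.cumsum(mask)])
        n_dA = cum[ends] - cum[starts]
        pos = np.array(sites.positions(chrom), dtype=int)
        idx = np.clip(pos // width, 0, n_bins - 1) if len(pos) else pos
        n_sites = np.bincount(idx, minlength=n_bins) if len(pos) else np.zeros(n_bins, int)
        with np.errstate(divide="ignore", invalid="ignore"):
            pct = np.where(n_dA > 0, 100.0 * n_sites / n_dA, np.nan)
        out[chrom] = pd.DataFrame(
            {
                "bin_start": starts,
                "bin_end": ends,
                "n_m6dA": n_sites,
                "n_dA": n_dA,
                "pct_m6dA_dA": pct,
            }
        )
    return out


# ---------------------------------------------------------------------------
# Fold enrichment with permutation significance
# ---------------------------------------------------------------------------

def feature_fold_enrichment(
    sites: SiteSet,
    annotation: GenomeAnnotation,
    genome: Dict[str, str],
    n_perm: int = 1000,
    seed: int = 0,
    exclude: Optional[Dict[str, List[Tuple[int, int]]]] = None,
    label_map: Optional[LabelMap] = None,
) -> pd.DataFrame:
    """Fold enrichment of m6dA density per feature with permutation p-values.

    fold = (m6dA_f / dA_f) / (m6dA_total / dA_total); the null distribution
    comes from re-placing the same number of sites uniformly on the
    strand-specific dA universe (per chromosome) and re-computing folds;
    p is two-sided on |fold - 1| with the (b + 1)/N convention.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    lm = label_map or build_label_map(annotation)
    n_feat = len(FEATURE_LABELS)

    # dA count per feature and flattened universe with per-position labels.
    dA_counts = np.zeros(n_feat, dtype=np.int64)
    pool_labels: List[np.ndarray] = []
    pool_counts: List[int] = []
    chrom_order = sorted(genome)
    for chrom in chrom_order:
        mask = _dA_mask(genome[chrom])
        if exclude and chrom in exclude:
            for a, b in exclude[chrom]:
                mask[max(0, a):min(len(mask), b)] = False
        labels = lm.labels[chrom]
        # strand-specific: an A position and a T position each count once;
        # both strands of a position share the positional label.
        arr = np.frombuffer(genome[chrom].upper().encode("ascii"), dtype=np.uint8)
        lab_at_dA = np.concatenate(
            [labels[mask & (arr == ord("A"))], labels[mask & (arr == ord("T"))]]
        )
        dA_counts += np.bincount(lab_at_dA, minlength=n_feat)
        pool_labels.append(lab_at_dA)
        pool_counts.append(0)

    site_counts = np.zeros(n_feat, dtype=np.int64)
    per_chrom_sites = {c: 0 for c in chrom_order}
    for a in assign_features(sites, annotation, lm):
        site_counts[_LABEL_CODE[a.feature]] += 1
        per_chrom_sites[a.site[0]] += 1

    total_sites = site_counts.sum()
    total_dA = dA_counts.sum()

    def folds(counts: np.ndarray) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            dens = np.where(dA_counts > 0, counts / dA_counts, np.nan)
        overall = total_sites / total_dA
        return dens / overall

    obs_fold = folds(site_counts)

    rng = np.random.default_rng(seed)
    null_folds = np.empty((n_perm, n_feat))
    for it in range(n_perm):
        counts = np.zeros(n_feat, dtype=np.int64)
        for ci, chrom in enumerate(chrom_order):
            n = per_chrom_sites[chrom]
            if n == 0:
                continue
            pool = pool_labels[ci]
            idx = rng.choice(len(pool), size=n, replace=False)
            counts += np.bincount(pool[idx], minlength=n_feat)
        null_folds[it] = folds(counts)

    rows = []
    for i, feature in enumerate(FEATURE_LABELS):
        if dA_counts[i] == 0:
            rows.append(
                {
                    "feature": feature,
                    "n_m6dA": int(site_counts[i]),
                    "n_dA": 0,
                    "fold": np.nan,
                    "pvalue": np.nan,
                }
            )
            continue
        p = empirical_pvalue(
            abs(obs_fold[i] - 1.0),
            np.abs(null_folds[:, i] - 1.0),
            alternative="greater",
        )
        rows.append(
            {
                "feature": feature,
                "n_m6dA": int(site_counts[i]),
                "n_dA": int(dA_counts[i]),
                "fold": float(obs_fold[i]),
                "pvalue": p,
            }
        )
    return pd.DataFrame(rows)
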