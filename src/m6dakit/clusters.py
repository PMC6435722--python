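"""Dense-6mA cluster detection and characterization.

A cluster seed is any 500 bp window anchored at a site position that
contains at least 10 called sites (strands pooled by genomic position);
overlapping qualifying windows are merged into maximal clusters and every
site inside a merged span is a cluster member. Remaining sites are "single".
"""

from __future__ import annotations

from typing import Dict, List, Tuple

import numpy as np
import pandas as pd

from .stats import ShuffleUniverse, empirical_pvalue, proportions_test, ranksum, shuffle_sites
from .types import Cluster, FEATURE_LABELS, SiteKey, SiteSet


def detect_clusters(
    sites: SiteSet,
    window: int = 500,
    min_sites: int = 10,
) -> Tuple[List[Cluster], SiteSet]:
    """Find merged dense regions and split sites into (clusters, singles)."""
    if window <= 0 or min_sites <= 0:
        raise ValueError("window and min_sites must be positive")
    clusters: List[Cluster] = []
    single_keys: List[SiteKey] = []
    for chrom in sites.chroms():
        members = sorted(sites.by_chrom(chrom), key=lambda s: (s.pos, s.strand))
        pos = np.array([s.pos for s in members], dtype=int)
        n = len(pos)
        # Anchored seed windows [p_i, p_i + window) with >= min_sites records.
        seeds: List[Tuple[int, int]] = []
        j = 0
        for i in range(n):
            if i > 0 and pos[i] == pos[i - 1]:
                continue
            hi = int(np.searchsorted(pos, pos[i] + window, side="left"))
            if hi - i >= min_sites:
                seeds.append((int(pos[i]), int(pos[i]) + window))
        # Merge overlapping seeds.
        merged: List[List[int]] = []
        for a, b in seeds:
            if merged and a <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], b)
            else:
                merged.append([a, b])
        in_cluster = np.zeros(n, dtype=bool)
        for a, b in merged:
            lo = int(np.searchsorted(pos, a, side="left"))
            hi = int(np.searchsorted(pos, b, side="left"))
            in_cluster[lo:hi] = True
            clusters.append(
                Cluster(
                    chrom=chrom,
                    start=a,
                    end=b,
                    members=[members[k].key for k in range(lo, hi)],
                )
            )
        single_keys.extend(members[k].key for k in range(n) if not in_cluster[k])
    return clusters, sites.subset(single_keys)


def cluster_stats(
    clusters: List[Cluster],
    genome: Dict[str, str],
) -> pd.DataFrame:
    """Per-cluster A/T fraction and median inter-site distance (in place).

    Distances are successive differences of member positions within each
    cluster. Returns a tidy per-cluster table; the global medians can be
    taken column-wise.
    """
    rows = []
    for c in clusters:
        if c.chrom not in genome:
            raise ValueError(f"cluster on unknown chromosome {c.chrom}")
        seq = genome[c.chrom]
        if c.end > len(seq) or c.start < 0:
            raise ValueError(f"cluster span [{c.start},{c.end}) outside {c.chrom}")
        region = seq[c.start:c.end].upper()
        at = (region.count("A") + region.count("T")) / len(region)
        pos = sorted(p for _, p, _ in c.members)
        diffs = np.diff(pos)
        med = float(np.median(diffs)) if len(diffs) else np.nan
        c.at_fraction = at
        c.median_distance = med
        rows.append(
            {
                "chrom": c.chrom,
                "start": c.start,
                "end": c.end,
                "n_members": c.n_members,
                "at_fraction": at,
                "median_distance": med,
            }
        )
    return pd.DataFrame(rows)


def clustered_fraction(sites: SiteSet, clusters: List[Cluster]) -> float:
    """Fraction of sites that fall inside clusters."""
    if len(sites) == 0:
        return 0.0
    n_in = sum(c.n_members for c in clusters)
    return n_in / len(sites)


def cluster_abundance_pvalue(
    sites: SiteSet,
    universe: ShuffleUniverse,
    n_perm: int = 1000,
    seed: int = 0,
    window: int = 500,
    min_sites: int = 10,
) -> Tuple[float, float]:
    """Permutation p-value for the fraction of sites found in clusters.

    The observed statistic is compared against shuffled site sets
    re-clustered with identical parameters; p = (exceedances + 1) / N.
    Returns (observed fraction, p).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    obs_clusters, _ = detect_clusters(sites, window, min_sites)
    obs = clustered_fraction(sites, obs_clusters)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for i in range(n_perm):
        shuffled = shuffle_sites(sites, universe, rng)
        cl, _ = detect_clusters(shuffled, window, min_sites)
        null[i] = clustered_fraction(shuffled, cl)
    return obs, empirical_pvalue(obs, null, alternative="greater")


def compare_cluster_vs_single(
    clustered: SiteSet,
    single: SiteSet,
    feature_of: Dict[SiteKey, str],
) -> Dict[str, object]:
    """Contrast cluster vs single sites in feature placement and fraction.

    Per feature, a continuity-corrected 2x2 proportions test of membership
    (in-feature vs not) between the two groups; plus a two-sided rank-sum
    test on methylated fraction with the difference of group medians.
    """
    if len(clustered) == 0 or len(single) == 0:
        raise ValueError("both cluster and single groups must be nonempty")
    rows = []
    n_c, n_s = len(clustered), len(single)
    for feature in FEATURE_LABELS:
        c_in = sum(1 for s in clustered if feature_of[s.key] == feature)
        s_in = sum(1 for s in single if feature_of[s.key] == feature)
        stat, p = proportions_test([[c_in, n_c - c_in], [s_in, n_s - s_in]])
        rows.append(
            {
                "feature": feature,
                "cluster_in": c_in,
                "single_in": s_in,
                "cluster_prop": c_in / n_c,
                "single_prop": s_in / n_s,
                "statistic": stat,
                "pvalue": p,
            }
        )
    frac_c = [s.meth_fraction for s in clustered]
    frac_s = [s.meth_fraction for s in single]
    return {
        "feature_tests": pd.DataFrame(rows),
        "fraction_pvalue": ranksum(frac_c, frac_s),
        "fraction_median_diff": float(np.median(frac_c) - np.median(frac_s)),
    }


def clusters_to_bed(clusters: List[Cluster]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chrom": c.chrom,
                "start": c.start,
                "end": c.end,
                "name": f"cluster_{i}",
                "n_members": c.n_members,
                "at_fraction": c.at_fraction,
                "median_distance": c.median_distance,
            }
            for i, c in enumerate(clusters)
        ]
    )
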