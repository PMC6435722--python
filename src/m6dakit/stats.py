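"""Shared resampling and classical-test layer.

Genome-aware shuffles of called sites, empirical p-values with the
(exceedances + 1) / N convention (minimum 1/N, so 0.001 at 1,000 shuffles),
interval/site overlap counting, and thin wrappers over the classical tests
the pipeline relies on (proportions/chi-squared, Fisher, hypergeometric,
rank-sum, binomial, Benjamini-Hochberg).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .types import KineticSite, SiteSet


# ---------------------------------------------------------------------------
# Shuffle universe and site shuffling
# ---------------------------------------------------------------------------

@dataclass
class ShuffleUniverse:
    """Strand-specific index of assayable adenosine positions per chromosome.

    An adenosine on the plus strand is an ``A`` in the reference sequence; an
    adenosine on the minus strand is a reference ``T``. Optional exclusion
    regions (e.g. centromeres) are removed at construction.
    """

    positions: Dict[str, Dict[str, np.ndarray]]  # chrom -> strand -> sorted pos

    @classmethod
    def from_genome(
        cls,
        genome: Dict[str, str],
        exclude: Optional[Dict[str, List[Tuple[int, int]]]] = None,
    ) -> "ShuffleUniverse":
        positions: Dict[str, Dict[str, np.ndarray]] = {}
        for chrom, seq in genome.items():
            arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
            plus = np.nonzero(arr == ord("A"))[0]
            minus = np.nonzero(arr == ord("T"))[0]
            if exclude and chrom in exclude:
                mask_len = len(seq)
                bad = np.zeros(mask_len, dtype=bool)
                for a, b in exclude[chrom]:
                    bad[max(0, a):min(mask_len, b)] = True
                plus = plus[~bad[plus]]
                minus = minus[~bad[minus]]
            positions[chrom] = {"+": plus, "-": minus}
        return cls(positions)

    def n_positions(self, chrom: str) -> int:
        d = self.positions[chrom]
        return len(d["+"]) + len(d["-"])

    def total(self) -> int:
        return sum(self.n_positions(c) for c in self.positions)


def shuffle_sites(
    sites: SiteSet,
    universe: ShuffleUniverse,
    rng: np.random.Generator,
    across_chromosomes: bool = False,
) -> SiteSet:
    """Resample site locations uniformly from the dA universe.

    Per-chromosome site counts are preserved by default (set
    ``across_chromosomes=True`` for a genome-wide shuffle). Strand follows the
    universe's dA strand composition because positions are drawn from the
    pooled strand-specific index without replacement.
    """
    out: List[KineticSite] = []
    sites_list = list(sites)
    if across_chromosomes:
        groups = {None: sites_list}
    else:
        groups = {}
        for s in sites_list:
            groups.setdefault(s.chrom, []).append(s)

    # Flatten universe (chrom, pos, strand) within each group.
    for group_chrom in sorted(groups, key=str):
        members = groups[group_chrom]
        chroms = (
            sorted(universe.positions) if group_chrom is None else [group_chrom]
        )
        pool_chrom: List[str] = []
        pool_pos: List[np.ndarray] = []
        pool_strand: List[str] = []
        for c in chroms:
            if c not in universe.positions:
                raise ValueError(f"universe does not cover chromosome {c}")
            for strand in ("+", "-"):
                pos = universe.positions[c][strand]
                pool_pos.append(pos)
                pool_chrom.extend([c] * len(pos))
                pool_strand.extend([strand] * len(pos))
        pos_flat = np.concatenate(pool_pos) if pool_pos else np.array([], int)
        n_pool = len(pos_flat)
        if len(members) > n_pool:
            raise ValueError(
                f"cannot place {len(members)} sites in a universe of {n_pool}"
            )
        idx = rng.choice(n_pool, size=len(members), replace=False)
        for site, i in zip(members, idx):
            out.append(
                site.with_fields(
                    chrom=pool_chrom[i],
                    pos=int(pos_flat[i]),
                    strand=pool_strand[i],
                    context=None,
                )
            )
    return SiteSet(out)


# ---------------------------------------------------------------------------
# Empirical p-values
# ---------------------------------------------------------------------------

def empirical_pvalue(
    observed: float,
    null_draws: Sequence[float],
    alternative: str = "greater",
) -> float:
    """Permutation p-value with the (exceedances + 1) / N convention.

    With N = 1,000 draws and an observed statistic exceeding every null draw
    this floors at 0.001. ``alternative`` is ``greater``, ``less`` or
    ``two-sided`` (two-sided compares |null| against |observed|).
    """
    null = np.asarray(null_draws, dtype=float)
    if null.size == 0:
        raise ValueError("need at least one null draw")
    if alternative == "greater":
        b = int(np.sum(null >= observed))
    elif alternative == "less":
        b = int(np.sum(null <= observed))
    elif alternative == "two-sided":
        b = int(np.sum(np.abs(null) >= abs(observed)))
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return min(1.0, (b + 1) / null.size)


# ---------------------------------------------------------------------------
# Overlaps
# ---------------------------------------------------------------------------

def overlap_exact(a: SiteSet, b: SiteSet) -> int:
    """Number of (chrom, pos, strand) keys present in both sets."""
    return len(set(a.keys()) & set(b.keys()))


def _merge_intervals(iv: List[Tuple[int, int]]) -> List[Tuple[int, int]]:
    if not iv:
        return []
    iv = sorted(iv)
    out = [list(iv[0])]
    for a, b in iv[1:]:
        if a <= out[-1][1]:
            out[-1][1] = max(out[-1][1], b)
        else:
            out.append([a, b])
    return [(a, b) for a, b in out]


@dataclass
class WindowedOverlap:
    """Shared flanked regions between two site sets."""

    n_regions: int
    members_a: int
    members_b: int


def overlap_windowed(a: SiteSet, b: SiteSet, flank: int = 250) -> WindowedOverlap:
    """Overlap after adding ``flank`` bp on either side of every site.

    Each set's flanked intervals are merged per chromosome; the shared regions
    are the merged intervals of the intersection. Reported are the number of
    shared regions and how many sites of each set fall inside them.
    """
    chroms = set(a.chroms()) | set(b.chroms())
    n_regions = 0
    members_a = 0
    members_b = 0
    for chrom in sorted(chroms):
        iv_a = _merge_intervals(
            [(s.pos - flank, s.pos + flank + 1) for s in a.by_chrom(chrom)]
        )
        iv_b = _merge_intervals(
            [(s.pos - flank, s.pos + flank + 1) for s in b.by_chrom(chrom)]
        )
        shared: List[Tuple[int, int]] = []
        i = j = 0
        while i < len(iv_a) and j < len(iv_b):
            lo = max(iv_a[i][0], iv_b[j][0])
            hi = min(iv_a[i][1], iv_b[j][1])
            if lo < hi:
                shared.append((lo, hi))
            if iv_a[i][1] < iv_b[j][1]:
                i += 1
            else:
                j += 1
        shared = _merge_intervals(shared)
        n_regions += len(shared)

        def _count(sites: List[KineticSite]) -> int:
            if not shared:
                return 0
            starts = np.array([s0 for s0, _ in shared])
            ends = np.array([e0 for _, e0 in shared])
            n = 0
            for s in sites:
                k = np.searchsorted(starts, s.pos, side="right") - 1
                if k >= 0 and s.pos < ends[k]:
                    n += 1
            return n

        members_a += _count(a.by_chrom(chrom))
        members_b += _count(b.by_chrom(chrom))
    return WindowedOverlap(n_regions, members_a, members_b)


# ---------------------------------------------------------------------------
# Classical test contracts
# ---------------------------------------------------------------------------

def proportions_test(table: Sequence[Sequence[float]]) -> Tuple[float, float]:
    """Pearson chi-squared test of equal proportions on a k x 2 count table.

    Mirrors R's ``prop.test``: Yates continuity correction on 2 x 2 tables,
    none for k > 2. Rows are groups, columns (successes, failures). A table
    with identical proportions returns statistic 0, p-value 1.
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.shape[1] != 2:
        raise ValueError("expected a k x 2 table of (successes, failures)")
    if (t < 0).any():
        raise ValueError("counts must be nonnegative")
    props = t[:, 0] / t.sum(axis=1)
    if np.allclose(props, props[0]):
        return 0.0, 1.0
    correction = t.shape[0] == 2
    chi2, p, _, _ = sps.chi2_contingency(t, correction=correction)
    return float(chi2), float(p)


def fisher_exact(table: Sequence[Sequence[int]]) -> Tuple[float, float]:
    """Two-sided Fisher's exact test on a 2 x 2 table; returns (odds ratio, p)."""
    t = np.asarray(table, dtype=int)
    if (t < 0).any():
        raise ValueError("counts must be nonnegative")
    odds, p = sps.fisher_exact(t, alternative="two-sided")
    return float(odds), float(p)


def hypergeometric_overlap(n_a: int, n_b: int, overlap: int, universe: int) -> float:
    """Upper-tail P(X >= overlap) when drawing |B| items from a universe
    containing |A| marked items."""
    if min(n_a, n_b, overlap, universe) < 0:
        raise ValueError("counts must be nonnegative")
    if overlap > min(n_a, n_b) or max(n_a, n_b) > universe:
        raise ValueError("inconsistent overlap counts")
    return float(sps.hypergeom.sf(overlap - 1, universe, n_a, n_b))


def ranksum(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value."""
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be nonempty")
    return float(sps.mannwhitneyu(x, y, alternative="two-sided").pvalue)


def binomial_two_sided(k: int, n: int, p0: float = 0.5) -> float:
    """Two-sided exact binomial test of k successes in n trials."""
    if not 0 <= k <= n:
        raise ValueError("need 0 <= k <= n")
    return float(sps.binomtest(k, n, p0, alternative="two-sided").pvalue)


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (monotone, order preserving)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]
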