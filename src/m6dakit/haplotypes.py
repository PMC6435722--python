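"""Haplotype-resolved 6mA calling and family-trio analysis.

Phased molecules are split by haplotype tag and the calling layer is applied
independently to HP1, HP2 and the pooled (diploid) molecule sets. Untagged
molecules contribute to the diploid calls only. The haplotype call table
applies the inclusion rule: found in the diploid analysis and at least 20x
coverage on each haplotig.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Optional, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .calling import CallingParams, call_from_molecules, filter_sites, methylated_cell_count
from .stats import bh_adjust, empirical_pvalue, overlap_exact, proportions_test
from .types import MoleculeObservation, SiteKey, SiteSet


@dataclass
class HaplotypeCalls:
    """Per-haplotype call sets plus the assembled per-site table."""

    diploid_called: SiteSet
    hp1_called: SiteSet
    hp2_called: SiteSet
    table: pd.DataFrame  # per site: *_fraction, *_coverage, included flag


def split_and_call_by_haplotype(
    molecules: Iterable[MoleculeObservation],
    params: Optional[CallingParams] = None,
) -> HaplotypeCalls:
    """Call sites independently on HP1, HP2 and pooled molecules.

    Raises if no molecule carries a haplotype tag (nothing to split).
    """
    params = params or CallingParams()
    mols = list(molecules)
    if not any(m.haplotype_tag != "untagged" for m in mols):
        raise ValueError("all molecules are untagged; nothing to split")
    hp1 = [m for m in mols if m.haplotype_tag == "HP1"]
    hp2 = [m for m in mols if m.haplotype_tag == "HP2"]

    diploid_sites = call_from_molecules(mols, params)
    hp1_sites = call_from_molecules(hp1, params)
    hp2_sites = call_from_molecules(hp2, params)

    diploid_called, _ = filter_sites(diploid_sites, params)
    hp1_called, _ = filter_sites(hp1_sites, params)
    hp2_called, _ = filter_sites(hp2_sites, params)

    rows = []
    for s in diploid_sites:
        k = s.key
        s1, s2 = hp1_sites.get(k), hp2_sites.get(k)
        c1 = s1.coverage if s1 else 0
        c2 = s2.coverage if s2 else 0
        rows.append(
            {
                "chrom": k[0],
                "pos": k[1],
                "strand": k[2],
                "diploid_fraction": s.meth_fraction,
                "diploid_coverage": s.coverage,
                "diploid_ipd_ratio": s.ipd_ratio,
                "hp1_fraction": s1.meth_fraction if s1 else np.nan,
                "hp1_coverage": c1,
                "hp2_fraction": s2.meth_fraction if s2 else np.nan,
                "hp2_coverage": c2,
                "included": (
                    k in diploid_called
                    and c1 >= params.min_coverage
                    and c2 >= params.min_coverage
                ),
            }
        )
    return HaplotypeCalls(
        diploid_called=diploid_called,
        hp1_called=hp1_called,
        hp2_called=hp2_called,
        table=pd.DataFrame(rows),
    )


@dataclass
class ExclusivityResult:
    hp1_only: int
    hp2_only: int
    both: int
    permutation_p: Optional[float] = None

    @property
    def single_haplotype_fraction(self) -> float:
        total = self.hp1_only + self.hp2_only + self.both
        return (self.hp1_only + self.hp2_only) / total if total else np.nan


def haplotype_exclusivity(
    hp1_called: SiteSet,
    hp2_called: SiteSet,
    universe=None,
    n_perm: int = 1000,
    seed: int = 0,
) -> ExclusivityResult:
    """Partition haplotype calls into HP1-only / HP2-only / both.

    With a :class:`~m6dakit.stats.ShuffleUniverse` given, a permutation
    p-value for the between-haplotype overlap is computed by re-placing both
    call sets uniformly on the dA universe.
    """
    k1, k2 = set(hp1_called.keys()), set(hp2_called.keys())
    both = len(k1 & k2)
    res = ExclusivityResult(
        hp1_only=len(k1) - both, hp2_only=len(k2) - both, both=both
    )
    if universe is not None:
        from .stats import shuffle_sites

        rng = np.random.default_rng(seed)
        null = np.empty(n_perm)
        for i in range(n_perm):
            a = shuffle_sites(hp1_called, universe, rng)
            b = shuffle_sites(hp2_called, universe, rng)
            null[i] = overlap_exact(a, b)
        res.permutation_p = empirical_pvalue(both, null, alternative="greater")
    return res


def single_haplotype_fraction(
    calls: HaplotypeCalls,
    params: Optional[CallingParams] = None,
    partner_max_fraction: float = 0.25,
) -> float:
    """Share of haplotype-called sites methylated on exactly one haplotype.

    A site called on one haplotype counts as exclusive only when the other
    haplotig has informative coverage (>= min_coverage) and shows no
    methylation evidence (estimated fraction < ``partner_max_fraction``);
    a partner merely failing the IPD-ratio call threshold but with an
    intermediate fraction counts as methylated on both. This keeps the
    measure calibrated at call-threshold boundaries.
    """
    params = params or CallingParams()
    k1, k2 = set(calls.hp1_called.keys()), set(calls.hp2_called.keys())
    tab = calls.table.set_index(["chrom", "pos", "strand"])
    single = both = 0
    for k in sorted(k1 | k2):
        row = tab.loc[k]
        if row["hp1_coverage"] < params.min_coverage or row["hp2_coverage"] < params.min_coverage:
            continue
        if k in k1 and k in k2:
            both += 1
            continue
        partner_frac = row["hp2_fraction"] if k in k1 else row["hp1_fraction"]
        if partner_frac < partner_max_fraction:
            single += 1
        else:
            both += 1
    total = single + both
    return single / total if total else float("nan")


def regress_diploid_on_haplotypes(table: pd.DataFrame) -> pd.DataFrame:
    """OLS of diploid fraction on the two haplotype fractions (with
    intercept) over included sites; t-test p-values per coefficient.

    With balanced haplotype coverage the diploid fraction is the average of
    the haplotype fractions, so the construction weights are (0.5, 0.5).
    """
    sub = table[table["included"]].dropna(subset=["hp1_fraction", "hp2_fraction"])
    if len(sub) < 3:
        raise ValueError("need at least 3 included sites for the regression")
    X = sm.add_constant(
        sub[["hp1_fraction", "hp2_fraction"]].to_numpy(), has_constant="add"
    )
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("collinear design: haplotype fractions are degenerate")
    fit = sm.OLS(sub["diploid_fraction"].to_numpy(), X).fit()
    return pd.DataFrame(
        {
            "term": ["intercept", "hp1_fraction", "hp2_fraction"],
            "coef": fit.params,
            "se": fit.bse,
            "t": fit.tvalues,
            "pvalue": fit.pvalues,
        }
    )


def differential_gene_methylation(
    sample_a: SiteSet,
    sample_b: SiteSet,
    gene_of: Dict[SiteKey, Optional[str]],
    min_total_coverage: int = 1,
) -> pd.DataFrame:
    """Per-gene differential methylation between two samples.

    For each gene the methylated molecule count (round-half-up of
    fraction * coverage) and the coverage are summed over the union of
    positions methylated in either sample; the per-gene 2x2 proportions test
    (continuity corrected) compares the two pooled proportions, with BH
    adjustment across genes. Genes with zero coverage in a sample are
    excluded.
    """
    per_gene: Dict[str, Dict[str, int]] = {}
    union_keys = set(sample_a.keys()) | set(sample_b.keys())
    for k in sorted(union_keys):
        gid = gene_of.get(k)
        if gid is None:
            continue
        sa, sb = sample_a.get(k), sample_b.get(k)
        ma = methylated_cell_count(sa.meth_fraction, sa.coverage) if sa else 0
        mb = methylated_cell_count(sb.meth_fraction, sb.coverage) if sb else 0
        if ma == 0 and mb == 0:
            continue  # position methylated in neither sample
        d = per_gene.setdefault(gid, {"ma": 0, "ca": 0, "mb": 0, "cb": 0})
        d["ma"] += ma
        d["ca"] += sa.coverage if sa else 0
        d["mb"] += mb
        d["cb"] += sb.coverage if sb else 0
    rows = []
    for gid in sorted(per_gene):
        d = per_gene[gid]
        if d["ca"] < min_total_coverage or d["cb"] < min_total_coverage:
            continue
        stat, p = proportions_test(
            [[d["ma"], d["ca"] - d["ma"]], [d["mb"], d["cb"] - d["mb"]]]
        )
        rows.append(
            {
                "gene_id": gid,
                "meth_a": d["ma"],
                "cov_a": d["ca"],
                "meth_b": d["mb"],
                "cov_b": d["cb"],
                "statistic": stat,
                "pvalue": p,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=["gene_id", "meth_a", "cov_a", "meth_b", "cov_b", "statistic", "pvalue"],
    )
    if len(df):
        df["qvalue"] = bh_adjust(df["pvalue"].to_numpy())
    else:
        df["qvalue"] = []
    return df


# ---------------------------------------------------------------------------
# Trio
# ---------------------------------------------------------------------------

@dataclass
class TrioResult:
    totals: Dict[str, int]
    overlaps: Dict[Tuple[str, str], int]
    permutation_p: Dict[Tuple[str, str], float]
    relatedness: pd.DataFrame  # per parent: parent-parent vs parent-son test


_PAIRS = (("mother", "father"), ("mother", "son"), ("father", "son"))


def trio_analysis(
    sites: Dict[str, SiteSet],
    pools: Dict[str, SiteSet],
    n_perm: int = 1000,
    seed: int = 0,
) -> TrioResult:
    """Pairwise exact overlaps within a trio with permutation significance
    and the relatedness proportion test.

    The permutation null draws, for each member, a random set of the same
    size from that member's failed-filter pool and counts the overlap; p is
    (exceedances + 1) / N. The relatedness test compares, per parent, the
    proportion of the parent's sites shared with the other parent against
    the proportion of the son's sites shared with that parent (Pearson
    chi-squared on the 2x2 counts) - parents are genetically unrelated, so
    an excess on the parent-son side indicates inheritance.
    """
    for name in ("mother", "father", "son"):
        if name not in sites or name not in pools:
            raise ValueError(f"missing trio member {name!r}")
        if len(pools[name]) < len(sites[name]):
            raise ValueError(f"failed-filter pool smaller than call set for {name}")
    totals = {n: len(sites[n]) for n in ("mother", "father", "son")}
    overlaps = {pair: overlap_exact(sites[pair[0]], sites[pair[1]]) for pair in _PAIRS}

    rng = np.random.default_rng(seed)
    perm_p: Dict[Tuple[str, str], float] = {}
    if n_perm > 0:
        pool_keys = {n: pools[n].keys() for n in totals}
        for pair in _PAIRS:
            a_keys, b_keys = pool_keys[pair[0]], pool_keys[pair[1]]
            null = np.empty(n_perm)
            for i in range(n_perm):
                a = rng.choice(len(a_keys), size=totals[pair[0]], replace=False)
                b = rng.choice(len(b_keys), size=totals[pair[1]], replace=False)
                sa = {a_keys[j] for j in a}
                sb = {b_keys[j] for j in b}
                null[i] = len(sa & sb)
            perm_p[pair] = empirical_pvalue(
                overlaps[pair], null, alternative="greater"
            )

    rel_rows = []
    o_pp = overlaps[("mother", "father")]
    for parent in ("mother", "father"):
        o_ps = overlaps[(parent, "son")]
        n_parent = totals[parent]
        n_son = totals["son"]
        stat, p = proportions_test(
            [[o_pp, n_parent - o_pp], [o_ps, n_son - o_ps]]
        )
        rel_rows.append(
            {
                "parent": parent,
                "parent_parent_overlap": o_pp,
                "parent_total": n_parent,
                "parent_son_overlap": o_ps,
                "son_total": n_son,
                "statistic": stat,
                "pvalue": p,
            }
        )
    return TrioResult(
        totals=totals,
        overlaps=overlaps,
        permutation_p=perm_p,
        relatedness=pd.DataFrame(rel_rows),
    )


def strand_coverage_filter(total_coverage: float) -> int:
    """Strand-specific coverage floor: round-half-up of half the total
    genome coverage (SMRT reads each strand separately)."""
    import math

    return int(math.floor(total_coverage / 2.0 + 0.5))
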