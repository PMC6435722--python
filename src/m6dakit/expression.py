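"""Linking 6mA status to gene expression and allele-specific expression.

Genes are split by presence of at least one called site in a named feature
(promoter / exon / intron, or the gene-level union) and their TPM
distributions compared with a two-sided rank-sum test. Allele-specific
expression (ASE) is a two-sided binomial test on phased allele counts with
Benjamini-Hochberg adjustment; the ASE gene set is intersected with the
haplotype-differentially-methylated gene set under a hypergeometric test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Set

import numpy as np
import pandas as pd

from .stats import bh_adjust, binomial_two_sided, hypergeometric_overlap, ranksum


@dataclass
class TpmComparison:
    feature: str
    n_with: int
    n_without: int
    median_with: float
    median_without: float
    pvalue: float


def tpm_by_m6dA_status(
    expression: pd.DataFrame,
    genes_with_m6dA: Set[str],
    feature: str = "gene",
) -> TpmComparison:
    """Compare TPM of genes with vs without 6mA in the named feature.

    ``genes_with_m6dA`` is the set of gene ids carrying at least one called
    site in that feature. Rank-based, so invariant to monotone TPM
    rescaling. Raises if either group is empty.
    """
    if "gene_id" not in expression.columns or "tpm" not in expression.columns:
        raise ValueError("expression table needs gene_id and tpm columns")
    has = expression["gene_id"].isin(genes_with_m6dA)
    with_tpm = expression.loc[has, "tpm"].to_numpy()
    without_tpm = expression.loc[~has, "tpm"].to_numpy()
    if len(with_tpm) == 0 or len(without_tpm) == 0:
        raise ValueError(f"empty comparison group for feature {feature!r}")
    return TpmComparison(
        feature=feature,
        n_with=len(with_tpm),
        n_without=len(without_tpm),
        median_with=float(np.median(with_tpm)),
        median_without=float(np.median(without_tpm)),
        pvalue=ranksum(with_tpm, without_tpm),
    )


def ase_test(
    expression: pd.DataFrame,
    min_depth: int = 20,
    q_threshold: float = 0.05,
) -> pd.DataFrame:
    """Per-gene two-sided binomial test of allelic balance with BH control.

    Genes with phased counts totalling at least ``min_depth`` form the
    tested universe; the returned table carries p, q and an ``ase`` flag
    (q <= ``q_threshold``).
    """
    for col in ("gene_id", "hap1_count", "hap2_count"):
        if col not in expression.columns:
            raise ValueError(f"expression table needs column {col!r}")
    if (expression[["hap1_count", "hap2_count"]] < 0).any().any():
        raise ValueError("allele counts must be nonnegative")
    df = expression.copy()
    df["total"] = df["hap1_count"] + df["hap2_count"]
    df = df[df["total"] >= max(1, min_depth)].reset_index(drop=True)
    df["pvalue"] = [
        binomial_two_sided(int(k), int(n))
        for k, n in zip(df["hap1_count"], df["total"])
    ]
    df["qvalue"] = bh_adjust(df["pvalue"].to_numpy())
    df["ase"] = df["qvalue"] <= q_threshold
    return df[["gene_id", "hap1_count", "hap2_count", "total", "pvalue", "qvalue", "ase"]]


def ase_diffmeth_overlap(
    ase_genes: Set[str],
    diffmeth_genes: Set[str],
    universe: Set[str],
) -> Dict[str, float]:
    """Overlap of ASE genes with differentially methylated genes and its
    upper-tail hypergeometric p-value over the gene universe."""
    if not ase_genes <= universe or not diffmeth_genes <= universe:
        raise ValueError("gene sets must be contained in the universe")
    overlap = len(ase_genes & diffmeth_genes)
    p = hypergeometric_overlap(
        len(ase_genes), len(diffmeth_genes), overlap, len(universe)
    )
    return {
        "n_ase": len(ase_genes),
        "n_diffmeth": len(diffmeth_genes),
        "overlap": overlap,
        "universe": len(universe),
        "pvalue": p,
    }
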