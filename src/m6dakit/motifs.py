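"""Sequence-context motif enrichment around called 6mA sites.

Foreground contexts (called sites) are compared against the failed-filter
null set with per-motif two-sided Fisher's exact tests. In the default
"neighbor" mode a site carries dinucleotide XY iff XY equals the upstream
neighbor plus the methylated A, or the methylated A plus the downstream
neighbor; a windowed mode (occurrence anywhere in the +/-20 bp context) is
available behind a flag. Significant overlapping dinucleotides are merged
into 3-mer cores and chained 4-mers and re-tested the same way.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import List, Sequence

import pandas as pd

from .stats import fisher_exact
from .types import CONTEXT_CENTER

BASES = "ACGT"
DINUCLEOTIDES = ["".join(p) for p in product(BASES, repeat=2)]


@dataclass(frozen=True)
class MotifResult:
    motif: str
    fg_with: int
    fg_without: int
    null_with: int
    null_without: int
    odds_ratio: float
    pvalue: float


def _validate_contexts(contexts: Sequence[str], name: str) -> List[str]:
    if not contexts:
        raise ValueError(f"{name} context set is empty")
    out = []
    for c in contexts:
        cu = c.upper()
        if len(cu) != 2 * CONTEXT_CENTER + 1:
            raise ValueError(f"{name} context of length {len(cu)} (expected 41)")
        if cu[CONTEXT_CENTER] != "A":
            raise ValueError(f"{name} context center is {cu[CONTEXT_CENTER]!r}, not A")
        out.append(cu)
    return out


def _has_dinucleotide(context: str, dinuc: str, windowed: bool) -> bool:
    if windowed:
        return dinuc in context
    up = context[CONTEXT_CENTER - 1] + context[CONTEXT_CENTER]
    down = context[CONTEXT_CENTER] + context[CONTEXT_CENTER + 1]
    return dinuc == up or dinuc == down


def _has_core(context: str, core: str) -> bool:
    """True if ``core`` occurs covering the central A, with one of the core's
    A positions aligned at the center."""
    k = len(core)
    for offset, base in enumerate(core):
        if base != "A":
            continue
        start = CONTEXT_CENTER - offset
        if 0 <= start and start + k <= len(context) and context[start:start + k] == core:
            return True
    return False


def _test(motif: str, fg_hits: int, n_fg: int, null_hits: int, n_null: int) -> MotifResult:
    table = [[fg_hits, n_fg - fg_hits], [null_hits, n_null - null_hits]]
    odds, p = fisher_exact(table)
    return MotifResult(motif, fg_hits, n_fg - fg_hits, null_hits, n_null - null_hits, odds, p)


def dinucleotide_enrichment(
    foreground: Sequence[str],
    null: Sequence[str],
    windowed: bool = False,
) -> List[MotifResult]:
    """Fisher enrichment of each of the 16 dinucleotides, foreground vs null."""
    fg = _validate_contexts(foreground, "foreground")
    nl = _validate_contexts(null, "null")
    out = []
    for dinuc in DINUCLEOTIDES:
        fg_hits = sum(_has_dinucleotide(c, dinuc, windowed) for c in fg)
        null_hits = sum(_has_dinucleotide(c, dinuc, windowed) for c in nl)
        out.append(_test(dinuc, fg_hits, len(fg), null_hits, len(nl)))
    return out


def significant_dinucleotides(
    results: Sequence[MotifResult],
    alpha: float = 0.05,
    bonferroni: bool = True,
) -> List[MotifResult]:
    """Enriched dinucleotides passing the (Bonferroni-corrected) threshold."""
    cut = alpha / len(results) if bonferroni else alpha
    return [r for r in results if r.pvalue <= cut and r.odds_ratio > 1.0]


def combine_motifs(
    significant: Sequence[MotifResult],
    foreground: Sequence[str],
    null: Sequence[str],
) -> List[MotifResult]:
    """Merge overlapping significant dinucleotides and re-test the combined
    motifs.

    Every ordered pair (d1, d2) with d1[1] == d2[0] yields the 3-mer core
    d1 + d2[1]; chains of three dinucleotides yield 4-mers. A context carries
    a combined motif iff the motif occurs covering the methylated A with an A
    of the motif at the central position. Cores containing no A cannot cover
    the center and are dropped.
    """
    fg = _validate_contexts(foreground, "foreground")
    nl = _validate_contexts(null, "null")
    dinucs = [r.motif for r in significant]
    cores: List[str] = []
    for d1 in dinucs:
        for d2 in dinucs:
            if d1[1] == d2[0]:
                m3 = d1 + d2[1]
                if m3 not in cores and "A" in m3:
                    cores.append(m3)
            for d3 in dinucs:
                if d1[1] == d2[0] and d2[1] == d3[0]:
                    m4 = d1 + d2[1] + d3[1]
                    if m4 not in cores and "A" in m4:
                        cores.append(m4)
    out = []
    for core in cores:
        fg_hits = sum(_has_core(c, core) for c in fg)
        null_hits = sum(_has_core(c, core) for c in nl)
        out.append(_test(core, fg_hits, len(fg), null_hits, len(nl)))
    return out


def motif_table(results: Sequence[MotifResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "motif": r.motif,
                "fg_with": r.fg_with,
                "fg_without": r.fg_without,
                "null_with": r.null_with,
                "null_without": r.null_without,
                "odds_ratio": r.odds_ratio,
                "pvalue": r.pvalue,
            }
            for r in results
        ]
    )


def contexts_of(sites) -> List[str]:
    """Contexts of a SiteSet, erroring on missing ones."""
    out = []
    for s in sites:
        if s.context is None:
            raise ValueError(f"site {s.key} has no sequence context")
        out.append(s.context)
    return out
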