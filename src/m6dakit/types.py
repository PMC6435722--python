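"""Core domain types for strand-specific 6mA kinetic data.

All internal coordinates are 0-based, half-open, and strand-explicit: the two
strands of one genomic position are distinct assayable sites, because SMRT
sequencing reads each strand of the circular template independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, Iterator, List, Optional, Tuple

SiteKey = Tuple[str, int, str]  # (chrom, 0-based position, strand)

STRANDS = ("+", "-")

#: Length of the sequence context attached to each site (site at index 20).
CONTEXT_LEN = 41
CONTEXT_CENTER = 20


@dataclass(frozen=True)
class KineticSite:
    """One strand-specific adenosine with its kinetic summary.

    Parameters
    ----------
    chrom, pos, strand
        Genomic location; ``pos`` is 0-based, ``strand`` is ``+`` or ``-``.
    coverage
        Number of distinct molecules covering the site on that strand.
    ipd_ratio
        Observed / expected inter-pulse duration, dimensionless, >= 0.
    meth_fraction
        Fraction in [0, 1] of covering molecules called methylated.
    context
        Optional 41-base sequence (+/-20 bp) on the site's strand, with the
        adenosine at index 20.
    """

    chrom: str
    pos: int
    strand: str
    coverage: int = 0
    ipd_ratio: float = 1.0
    meth_fraction: float = 0.0
    context: Optional[str] = None

    def __post_init__(self) -> None:
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")
        if self.pos < 0:
            raise ValueError("position must be >= 0")
        if self.coverage < 0:
            raise ValueError("coverage must be >= 0")
        if self.ipd_ratio < 0:
            raise ValueError("ipd_ratio must be >= 0")
        if not 0.0 <= self.meth_fraction <= 1.0:
            raise ValueError("meth_fraction must lie in [0, 1]")
        if self.context is not None:
            if len(self.context) != CONTEXT_LEN:
                raise ValueError(
                    f"context must be {CONTEXT_LEN} bases, got {len(self.context)}"
                )
            if self.context[CONTEXT_CENTER].upper() != "A":
                raise ValueError("context center base must be A on the site strand")

    @property
    def key(self) -> SiteKey:
        return (self.chrom, self.pos, self.strand)

    def with_fields(self, **kw) -> "KineticSite":
        return replace(self, **kw)


@dataclass(frozen=True)
class MoleculeObservation:
    """Per-molecule inter-pulse-duration summary at one site.

    ``mean_log_ipd`` is the mean of log IPD over the molecule's sequencing
    passes; with ``n_passes`` passes its sampling variance scales as
    sigma^2 / n_passes under the log-normal kinetic model.
    """

    chrom: str
    pos: int
    strand: str
    molecule_id: int
    mean_log_ipd: float
    n_passes: int = 1
    haplotype_tag: str = "untagged"  # one of {"HP1", "HP2", "untagged"}

    def __post_init__(self) -> None:
        if self.n_passes < 1:
            raise ValueError("n_passes must be >= 1")
        if self.haplotype_tag not in ("HP1", "HP2", "untagged"):
            raise ValueError(f"invalid haplotype tag {self.haplotype_tag!r}")

    @property
    def site_key(self) -> SiteKey:
        return (self.chrom, self.pos, self.strand)


class SiteSet:
    """Ordered collection of :class:`KineticSite` keyed by (chrom, pos, strand).

    Keys are unique; iteration order is deterministic (chrom, pos, strand).
    """

    def __init__(self, sites: Iterable[KineticSite] = ()) -> None:
        self._sites: Dict[SiteKey, KineticSite] = {}
        for s in sites:
            self.add(s)

    def add(self, site: KineticSite) -> None:
        if site.key in self._sites:
            raise ValueError(f"duplicate site key {site.key}")
        self._sites[site.key] = site

    def __len__(self) -> int:
        return len(self._sites)

    def __contains__(self, key: SiteKey) -> bool:
        return key in self._sites

    def __getitem__(self, key: SiteKey) -> KineticSite:
        return self._sites[key]

    def get(self, key: SiteKey) -> Optional[KineticSite]:
        return self._sites.get(key)

    def __iter__(self) -> Iterator[KineticSite]:
        for key in sorted(self._sites):
            yield self._sites[key]

    def keys(self) -> List[SiteKey]:
        return sorted(self._sites)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SiteSet):
            return NotImplemented
        return self._sites == other._sites

    def chroms(self) -> List[str]:
        return sorted({c for c, _, _ in self._sites})

    def by_chrom(self, chrom: str) -> List[KineticSite]:
        return [s for s in self if s.chrom == chrom]

    def positions(self, chrom: str) -> List[int]:
        """Sorted site positions on ``chrom`` (strands pooled, duplicates kept)."""
        return sorted(p for c, p, _ in self._sites if c == chrom)

    def subset(self, keys: Iterable[SiteKey]) -> "SiteSet":
        return SiteSet(self._sites[k] for k in keys)


@dataclass(frozen=True)
class Transcript:
    """One transcript record with exon structure and optional UTRs."""

    gene_id: str
    chrom: str
    strand: str
    start: int  # transcript span, 0-based half-open
    end: int
    exons: Tuple[Tuple[int, int], ...]
    utr5: Tuple[Tuple[int, int], ...] = ()
    utr3: Tuple[Tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")
        for a, b in self.exons:
            if a < self.start or b > self.end:
                raise ValueError(
                    f"exon [{a},{b}) outside transcript span "
                    f"[{self.start},{self.end}) for {self.gene_id}"
                )

    @property
    def tss(self) -> int:
        """0-based transcription start site (strand aware)."""
        return self.start if self.strand == "+" else self.end - 1

    def promoter(self, upstream: int = 1000) -> Tuple[int, int]:
        """Region ``upstream`` bp upstream of the TSS, clipped at 0."""
        if self.strand == "+":
            return (max(0, self.start - upstream), self.start)
        return (self.end, self.end + upstream)

    def downstream(self, length: int = 1000) -> Tuple[int, int]:
        """Region up to ``length`` bp past the transcript end (strand aware)."""
        if self.strand == "+":
            return (self.end, self.end + length)
        return (max(0, self.start - length), self.start)

    def introns(self) -> List[Tuple[int, int]]:
        exons = sorted(self.exons)
        return [
            (exons[i][1], exons[i + 1][0])
            for i in range(len(exons) - 1)
            if exons[i + 1][0] > exons[i][1]
        ]


# Feature labels in assignment-precedence order (highest first).
FEATURE_LABELS = (
    "promoter",
    "utr5",
    "utr3",
    "exon",
    "intron",
    "downstream",
    "intergenic",
)


@dataclass
class GenomeAnnotation:
    """Transcript annotation with derived promoters, introns and intergenic space.

    ``chrom_sizes`` bounds the intergenic complement; promoters are 1 kb
    upstream of the TSS by convention.
    """

    transcripts: List[Transcript]
    chrom_sizes: Dict[str, int]
    promoter_upstream: int = 1000
    downstream_length: int = 1000

    def __post_init__(self) -> None:
        self.transcripts = sorted(
            self.transcripts, key=lambda t: (t.chrom, t.start, t.gene_id)
        )
        for t in self.transcripts:
            if t.chrom not in self.chrom_sizes:
                raise ValueError(f"transcript {t.gene_id} on unknown chrom {t.chrom}")
            if t.end > self.chrom_sizes[t.chrom]:
                raise ValueError(
                    f"transcript {t.gene_id} extends past end of {t.chrom}"
                )

    @property
    def gene_ids(self) -> List[str]:
        return sorted({t.gene_id for t in self.transcripts})

    def by_chrom(self, chrom: str) -> List[Transcript]:
        return [t for t in self.transcripts if t.chrom == chrom]


@dataclass
class Cluster:
    """A merged dense-6mA region (seed windows are 500 bp, >= 10 sites)."""

    chrom: str
    start: int
    end: int
    members: List[SiteKey] = field(default_factory=list)
    at_fraction: Optional[float] = None
    median_distance: Optional[float] = None

    @property
    def n_members(self) -> int:
        return len(self.members)

    @property
    def span(self) -> Tuple[int, int]:
        return (self.start, self.end)
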