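"""Readers and writers for every on-disk format the pipeline touches.

Two dialects carry kinetic site records:

* ``gff3-mod`` — a GFF3 modifications dialect (one feature line per strand-
  specific adenosine; attributes ``coverage``, ``IPDRatio``, ``frac``,
  ``context``), with the usual GFF 1-based inclusive coordinates.
* ``tabular`` — the package's versioned UTF-8 tab-separated table with
  0-based positions (header ``#m6dakit-kinetics v1``).

Internal coordinates are 0-based half-open everywhere; GFF input start
coordinates are shifted by -1 on read, BED is used as-is. Fractions are
stored in [0, 1]; a ``frac`` above 1 on input is interpreted as a percentage
and divided by 100.
"""

from __future__ import annotations

import os
from typing import Dict, Iterable, List, Optional, Tuple

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .types import (
    GenomeAnnotation,
    KineticSite,
    MoleculeObservation,
    SiteSet,
    Transcript,
)

TABULAR_HEADER = "#m6dakit-kinetics v1"
_TAB_COLS = ("chrom", "pos", "strand", "coverage", "ipd_ratio", "meth_fraction", "context")

MOLECULES_HEADER = "#m6dakit-molecules v1"
_MOL_COLS = ("chrom", "pos", "strand", "molecule_id", "mean_log_ipd", "n_passes", "haplotype_tag")


class ParseError(ValueError):
    """Raised for malformed records, naming the offending line."""


def _parse_fraction(raw: str, path: str, lineno: int) -> float:
    try:
        f = float(raw)
    except ValueError as e:
        raise ParseError(f"{path}:{lineno}: bad fraction {raw!r}") from e
    if f > 1.0:  # percent convention
        f = f / 100.0
    if not 0.0 <= f <= 1.0:
        raise ParseError(f"{path}:{lineno}: fraction {raw!r} out of range")
    return f


def _check_strand(strand: str, path: str, lineno: int) -> str:
    if strand not in ("+", "-"):
        raise ParseError(f"{path}:{lineno}: unknown strand symbol {strand!r}")
    return strand


# ---------------------------------------------------------------------------
# Kinetic site records
# ---------------------------------------------------------------------------

def read_modifications(path: str, dialect: str = "gff3-mod") -> SiteSet:
    """Read kinetic site records from a modifications file."""
    if dialect == "gff3-mod":
        return _read_mod_gff3(path)
    if dialect == "tabular":
        return _read_mod_tabular(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def write_modifications(sites: SiteSet, path: str, dialect: str = "gff3-mod") -> None:
    """Write kinetic site records; output is deterministic and round-trips."""
    if dialect == "gff3-mod":
        _write_mod_gff3(sites, path)
    elif dialect == "tabular":
        _write_mod_tabular(sites, path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def _read_mod_gff3(path: str) -> SiteSet:
    sites: List[KineticSite] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(f"{path}:{lineno}: expected 9 columns, got {len(fields)}")
            chrom, _, _, start, end, _, strand, _, attrs_raw = fields
            _check_strand(strand, path, lineno)
            try:
                pos = int(start) - 1
            except ValueError as e:
                raise ParseError(f"{path}:{lineno}: bad start {start!r}") from e
            if int(end) != pos + 1:
                raise ParseError(f"{path}:{lineno}: modification records span one base")
            attrs = {}
            for item in attrs_raw.split(";"):
                if item and "=" in item:
                    k, v = item.split("=", 1)
                    attrs[k] = v
            try:
                sites.append(
                    KineticSite(
                        chrom=chrom,
                        pos=pos,
                        strand=strand,
                        coverage=int(attrs["coverage"]),
                        ipd_ratio=float(attrs["IPDRatio"]),
                        meth_fraction=_parse_fraction(attrs["frac"], path, lineno),
                        context=attrs.get("context") or None,
                    )
                )
            except KeyError as e:
                raise ParseError(f"{path}:{lineno}: missing attribute {e}") from e
            except ValueError as e:
                raise ParseError(f"{path}:{lineno}: {e}") from e
    return SiteSet(sites)


def _write_mod_gff3(sites: SiteSet, path: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("##gff-version 3\n")
        for s in sites:
            attrs = [f"coverage={s.coverage}", f"IPDRatio={s.ipd_ratio!r}", f"frac={s.meth_fraction!r}"]
            if s.context is not None:
                attrs.append(f"context={s.context}")
            fh.write(
                f"{s.chrom}\tkinModCall\tm6A\t{s.pos + 1}\t{s.pos + 1}\t.\t{s.strand}\t.\t"
                + ";".join(attrs)
                + "\n"
            )


def _read_mod_tabular(path: str) -> SiteSet:
    sites: List[KineticSite] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("chrom\t"):
                continue
            fields = line.split("\t")
            if len(fields) != len(_TAB_COLS):
                raise ParseError(
                    f"{path}:{lineno}: expected {len(_TAB_COLS)} columns, got {len(fields)}"
                )
            chrom, pos, strand, cov, ratio, frac, ctx = fields
            _check_strand(strand, path, lineno)
            try:
                sites.append(
                    KineticSite(
                        chrom=chrom,
                        pos=int(pos),
                        strand=strand,
                        coverage=int(cov),
                        ipd_ratio=float(ratio),
                        meth_fraction=_parse_fraction(frac, path, lineno),
                        context=None if ctx in (".", "") else ctx,
                    )
                )
            except ValueError as e:
                raise ParseError(f"{path}:{lineno}: {e}") from e
    return SiteSet(sites)


def _write_mod_tabular(sites: SiteSet, path: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(TABULAR_HEADER + "\n")
        fh.write("\t".join(_TAB_COLS) + "\n")
        for s in sites:
            ctx = s.context if s.context is not None else "."
            fh.write(
                f"{s.chrom}\t{s.pos}\t{s.strand}\t{s.coverage}\t"
                f"{s.ipd_ratio!r}\t{s.meth_fraction!r}\t{ctx}\n"
            )


# ---------------------------------------------------------------------------
# Molecule observations
# ---------------------------------------------------------------------------

def write_molecules(molecules: Iterable[MoleculeObservation], path: str) -> None:
    mols = sorted(molecules, key=lambda m: (m.chrom, m.pos, m.strand, m.molecule_id))
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(MOLECULES_HEADER + "\n")
        fh.write("\t".join(_MOL_COLS) + "\n")
        for m in mols:
            fh.write(
                f"{m.chrom}\t{m.pos}\t{m.strand}\t{m.molecule_id}\t"
                f"{m.mean_log_ipd!r}\t{m.n_passes}\t{m.haplotype_tag}\n"
            )


def read_molecules(path: str) -> List[MoleculeObservation]:
    out: List[MoleculeObservation] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("chrom\t"):
                continue
            fields = line.split("\t")
            if len(fields) != len(_MOL_COLS):
                raise ParseError(f"{path}:{lineno}: expected {len(_MOL_COLS)} columns")
            chrom, pos, strand, mid, mli, np_, tag = fields
            _check_strand(strand, path, lineno)
            out.append(
                MoleculeObservation(
                    chrom=chrom,
                    pos=int(pos),
                    strand=strand,
                    molecule_id=int(mid),
                    mean_log_ipd=float(mli),
                    n_passes=int(np_),
                    haplotype_tag=tag,
                )
            )
    return out


# ---------------------------------------------------------------------------
# Genome, annotation, regions
# ---------------------------------------------------------------------------

def read_genome(path: str) -> Dict[str, str]:
    """Read a FASTA into a chrom -> uppercase sequence map."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


def write_genome(genome: Dict[str, str], path: str) -> None:
    records = [
        SeqRecord(Seq(genome[c]), id=c, description="") for c in sorted(genome)
    ]
    SeqIO.write(records, path, "fasta")


def read_regions(path: str) -> Dict[str, List[Tuple[int, int]]]:
    """Read a BED (>= 3 columns) into chrom -> sorted [start, end) intervals."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        usecols=[0, 1, 2],
        names=["chrom", "start", "end"],
        dtype={"chrom": str, "start": int, "end": int},
    )
    out: Dict[str, List[Tuple[int, int]]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(row.chrom, []).append((int(row.start), int(row.end)))
    return {c: sorted(v) for c, v in out.items()}


def write_regions(regions: Dict[str, List[Tuple[int, int]]], path: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for chrom in sorted(regions):
            for a, b in sorted(regions[chrom]):
                fh.write(f"{chrom}\t{a}\t{b}\n")


def read_annotation(
    path: str,
    chrom_sizes: Optional[Dict[str, int]] = None,
    promoter_upstream: int = 1000,
) -> GenomeAnnotation:
    """Load a gene-annotation GFF3 into a :class:`GenomeAnnotation`.

    Transcript models are assembled from ``mRNA``/``transcript`` features and
    their ``exon``/``five_prime_UTR``/``three_prime_UTR`` children (GFF
    ``Parent`` attributes). Chromosome sizes come from ``##sequence-region``
    pragmas unless given explicitly.
    """
    sizes: Dict[str, int] = dict(chrom_sizes or {})
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("##sequence-region"):
                parts = line.split()
                if len(parts) >= 4:
                    sizes.setdefault(parts[1], int(parts[3]))
            elif not line.startswith("#"):
                break

    db = gffutils.create_db(
        path,
        dbfn=":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    transcripts: List[Transcript] = []
    for feat in db.all_features():
        if feat.featuretype not in ("mRNA", "transcript"):
            continue
        gene_id = feat.attributes.get("gene_id", [feat.id])[0]
        exons, utr5, utr3 = [], [], []
        for child in db.children(feat.id):
            iv = (child.start - 1, child.end)  # 1-based inclusive -> 0-based half-open
            if child.featuretype == "exon":
                exons.append(iv)
            elif child.featuretype == "five_prime_UTR":
                utr5.append(iv)
            elif child.featuretype == "three_prime_UTR":
                utr3.append(iv)
        transcripts.append(
            Transcript(
                gene_id=gene_id,
                chrom=feat.seqid,
                strand=feat.strand,
                start=feat.start - 1,
                end=feat.end,
                exons=tuple(sorted(exons)),
                utr5=tuple(sorted(utr5)),
                utr3=tuple(sorted(utr3)),
            )
        )
    if not sizes:
        for t in transcripts:
            sizes[t.chrom] = max(sizes.get(t.chrom, 0), t.end)
    return GenomeAnnotation(
        transcripts=transcripts,
        chrom_sizes=sizes,
        promoter_upstream=promoter_upstream,
    )


def write_annotation(annotation: GenomeAnnotation, path: str) -> None:
    """Write transcripts as GFF3 (gene/mRNA/exon/UTR with ID/Parent links)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("##gff-version 3\n")
        for chrom in sorted(annotation.chrom_sizes):
            fh.write(
                f"##sequence-region {chrom} 1 {annotation.chrom_sizes[chrom]}\n"
            )
        for t in annotation.transcripts:
            gid, tid = t.gene_id, f"{t.gene_id}.t1"
            base = f"{t.chrom}\tm6dakit\t"
            tail = f"\t.\t{t.strand}\t.\t"
            fh.write(
                base + f"gene\t{t.start + 1}\t{t.end}" + tail
                + f"ID={gid};gene_id={gid}\n"
            )
            fh.write(
                base + f"mRNA\t{t.start + 1}\t{t.end}" + tail
                + f"ID={tid};Parent={gid};gene_id={gid}\n"
            )
            for i, (a, b) in enumerate(t.exons, 1):
                fh.write(
                    base + f"exon\t{a + 1}\t{b}" + tail
                    + f"ID={tid}.exon{i};Parent={tid};gene_id={gid}\n"
                )
            for i, (a, b) in enumerate(t.utr5, 1):
                fh.write(
                    base + f"five_prime_UTR\t{a + 1}\t{b}" + tail
                    + f"ID={tid}.utr5.{i};Parent={tid};gene_id={gid}\n"
                )
            for i, (a, b) in enumerate(t.utr3, 1):
                fh.write(
                    base + f"three_prime_UTR\t{a + 1}\t{b}" + tail
                    + f"ID={tid}.utr3.{i};Parent={tid};gene_id={gid}\n"
                )


# ---------------------------------------------------------------------------
# Phased SNPs and expression tables
# ---------------------------------------------------------------------------

def write_phased_snps(snps: pd.DataFrame, path: str) -> None:
    """Write a phased-SNP table (chrom, pos, ref, alt, hp1, hp2)."""
    snps.to_csv(path, sep="\t", index=False)


def read_phased_snps(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"chrom": str})


def write_expression(expr: pd.DataFrame, path: str) -> None:
    """Write a gene-level expression table (gene_id, tpm[, hap1_count, hap2_count])."""
    expr.to_csv(path, sep="\t", index=False)


def read_expression(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "gene_id" not in df.columns or "tpm" not in df.columns:
        raise ParseError(f"{path}: expression table needs gene_id and tpm columns")
    return df
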