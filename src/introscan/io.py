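"""Readers and writers for the external formats the pipeline touches.

Coordinate conventions
----------------------
External formats use their native conventions: VCF and GFF3 positions are
1-based (GFF3 intervals inclusive).  All *internal* interval arithmetic in
this package is 0-based half-open; :func:`to_internal` / :func:`to_external`
convert between the two.

Variant tables keep single-nucleotide substitutions only; indels and
symbolic alleles are dropped on read (the analyses downstream are defined
on SNPs).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gffutils
import numpy as np
import pandas as pd
import pysam
from Bio.Seq import Seq
from pyfaidx import Fasta

logger = logging.getLogger(__name__)

VARIANT_COLUMNS = ["chrom", "pos", "ref", "alt", "qual"]
_BASES = frozenset("ACGT")


class FormatError(ValueError):
    """Raised when an input file violates the expected subset of its format."""


# ---------------------------------------------------------------------------
# coordinate converters
# ---------------------------------------------------------------------------

def to_internal(start_1based: int, end_1based_inclusive: int) -> tuple[int, int]:
    """1-based inclusive interval -> 0-based half-open."""
    return start_1based - 1, end_1based_inclusive


def to_external(start0: int, end0: int) -> tuple[int, int]:
    """0-based half-open interval -> 1-based inclusive."""
    return start0 + 1, end0


# ---------------------------------------------------------------------------
# variant tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VariantCall:
    """A single-nucleotide substitution call in one strain."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    qual: float
    strain: str = ""

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos}")
        if len(self.ref) != 1 or len(self.alt) != 1:
            raise ValueError("only single-nucleotide ref/alt are supported")
        if self.qual < 0:
            raise ValueError("qual must be non-negative")


@dataclass
class StrainVariantTable:
    """Quality-filtered coding SNPs of one strain.

    ``variants`` has columns chrom, pos (1-based), ref, alt, qual.
    """

    strain: str
    variants: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=VARIANT_COLUMNS)
    )

    def __post_init__(self) -> None:
        missing = [c for c in VARIANT_COLUMNS if c not in self.variants.columns]
        if missing:
            raise ValueError(f"variant table missing columns {missing}")
        self.variants = self.variants[VARIANT_COLUMNS].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.variants)

    def key_set(self) -> set[tuple[str, int, str]]:
        """Set of (chrom, pos, alt) keys."""
        v = self.variants
        return set(zip(v.chrom, v.pos, v.alt))


def read_vcf(
    path: str | Path,
    strain: str | None = None,
    min_qual: float = 100.0,
    multiallelic: str = "split",
) -> StrainVariantTable:
    """Read a VCF into a :class:`StrainVariantTable`.

    Records with QUAL below ``min_qual`` are dropped (the pipeline's default
    of 100 mirrors the calling-quality filter used to produce reliable coding
    SNPs from RNA-Seq alignments).  Indels and symbolic alleles are dropped.
    Multi-allelic records are split into one row per alt allele by default;
    ``multiallelic="reject"`` raises instead.
    """
    path = Path(path)
    if multiallelic not in ("split", "reject"):
        raise ValueError("multiallelic must be 'split' or 'reject'")
    rows: list[tuple] = []
    n_dropped_qual = 0
    n_dropped_indel = 0
    try:
        vf = pysam.VariantFile(str(path))
    except (ValueError, OSError) as exc:
        raise FormatError(f"{path}: cannot parse VCF: {exc}") from exc
    with vf:
        for rec in vf:
            alts = rec.alts or ()
            if len(alts) > 1 and multiallelic == "reject":
                raise FormatError(
                    f"{path}: multi-allelic record at {rec.chrom}:{rec.pos}"
                )
            qual = rec.qual if rec.qual is not None else 0.0
            for alt in alts:
                if alt is None:
                    continue
                if len(rec.ref) != 1 or len(alt) != 1 or alt.upper() not in _BASES:
                    n_dropped_indel += 1
                    continue
                if qual < min_qual:
                    n_dropped_qual += 1
                    continue
                rows.append((rec.chrom, rec.pos, rec.ref.upper(), alt.upper(), qual))
    if n_dropped_qual or n_dropped_indel:
        logger.info(
            "%s: dropped %d records below QUAL %g and %d non-SNP alleles",
            path, n_dropped_qual, min_qual, n_dropped_indel,
        )
    df = pd.DataFrame(rows, columns=VARIANT_COLUMNS)
    return StrainVariantTable(strain=strain or path.stem, variants=df)


def write_vcf(
    table: StrainVariantTable,
    path: str | Path,
    contigs: dict[str, int] | None = None,
    seed: int | None = None,
) -> Path:
    """Write a variant table as a minimal VCF 4.2 file."""
    path = Path(path)
    v = table.variants.sort_values(["chrom", "pos", "alt"], kind="mergesort")
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##source=introscan strain={table.strain}")
        if seed is not None:
            fh.write(f" seed={seed}")
        fh.write("\n")
        for name, length in (contigs or {}).items():
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for row in v.itertuples(index=False):
            fh.write(
                f"{row.chrom}\t{row.pos}\t.\t{row.ref}\t{row.alt}\t"
                f"{row.qual:g}\tPASS\t.\n"
            )
    return path


# ---------------------------------------------------------------------------
# coverage tables (sites observed at the reference allele)
# ---------------------------------------------------------------------------

def read_covered_sites(path: str | Path) -> pd.DataFrame:
    """Read a TSV of reference-agreeing covered sites (chrom, pos)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "pos": np.int64})
    if not {"chrom", "pos"}.issubset(df.columns):
        raise FormatError(f"{path}: expected columns chrom, pos")
    return df[["chrom", "pos"]]


def write_covered_sites(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    df = df[["chrom", "pos"]].sort_values(["chrom", "pos"], kind="mergesort")
    df.to_csv(path, sep="\t", index=False)
    return path


# ---------------------------------------------------------------------------
# gene models
# ---------------------------------------------------------------------------

@dataclass
class GeneModel:
    """A protein-coding gene with stitched CDS.

    ``cds_intervals`` are 1-based inclusive genomic intervals ordered 5'→3'
    in transcript orientation (so for minus-strand genes the first interval
    has the largest coordinates).  ``coding_sequence`` is in coding
    orientation and its length equals the summed interval length.
    """

    gene_id: str
    symbol: str
    chrom: str
    strand: str
    cds_intervals: list[tuple[int, int]]
    coding_sequence: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        total = sum(e - s + 1 for s, e in self.cds_intervals)
        if total % 3 != 0:
            raise ValueError(
                f"{self.gene_id}: CDS length {total} is not a multiple of 3"
            )
        if len(self.coding_sequence) != total:
            raise ValueError(
                f"{self.gene_id}: coding sequence length "
                f"{len(self.coding_sequence)} != CDS length {total}"
            )
        ivs = sorted((s, e) for s, e in self.cds_intervals)
        for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
            if s2 <= e1:
                raise ValueError(f"{self.gene_id}: overlapping CDS intervals")
        self.coding_sequence = self.coding_sequence.upper()

    @property
    def cds_length(self) -> int:
        return len(self.coding_sequence)

    @property
    def span(self) -> tuple[int, int]:
        """Genomic footprint as a 0-based half-open interval."""
        start = min(s for s, _ in self.cds_intervals)
        end = max(e for _, e in self.cds_intervals)
        return to_internal(start, end)

    def genomic_to_cds(self, pos: int) -> int:
        """Map a 1-based genomic position to a 1-based CDS offset."""
        offset = 0
        for s, e in self.cds_intervals:
            if s <= pos <= e:
                if self.strand == "+":
                    return offset + (pos - s) + 1
                return offset + (e - pos) + 1
            offset += e - s + 1
        raise ValueError(
            f"position {self.chrom}:{pos} is outside the CDS of {self.gene_id}"
        )

    def cds_to_genomic(self, cds_pos: int) -> int:
        """Map a 1-based CDS offset to a 1-based genomic position."""
        if not 1 <= cds_pos <= self.cds_length:
            raise ValueError(f"CDS position {cds_pos} out of range")
        remaining = cds_pos - 1
        for s, e in self.cds_intervals:
            n = e - s + 1
            if remaining < n:
                return s + remaining if self.strand == "+" else e - remaining
            remaining -= n
        raise AssertionError("unreachable")


def _transcript_oriented(intervals: list[tuple[int, int]], strand: str):
    return sorted(intervals, reverse=(strand == "-"))


def read_gff(path: str | Path, fasta_path: str | Path) -> list[GeneModel]:
    """Read gene models from a GFF3 subset plus a FASTA.

    The FASTA may contain either chromosome sequences (CDS is sliced out and
    minus-strand genes reverse-complemented) or per-transcript coding
    sequences keyed by mRNA/gene ID (already in coding orientation).  Models
    whose CDS length is not a multiple of 3, or whose CDS intervals overlap,
    are excluded with a warning.
    """
    path, fasta_path = Path(path), Path(fasta_path)
    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    fasta = Fasta(str(fasta_path), as_raw=True, sequence_always_upper=True)
    models: list[GeneModel] = []
    for gene in db.features_of_type("gene"):
        gene_id = gene.id
        symbol = gene.attributes.get("Name", [gene_id])[0]
        mrnas = list(db.children(gene, featuretype="mRNA")) or [gene]
        mrna = mrnas[0]  # one representative transcript per gene
        cds = list(db.children(mrna, featuretype="CDS"))
        if not cds:
            cds = list(db.children(gene, featuretype="CDS"))
        if not cds:
            continue
        intervals = _transcript_oriented([(c.start, c.end) for c in cds], gene.strand)
        try:
            if gene.chrom in fasta:
                chunks = []
                for s, e in intervals:
                    piece = str(fasta[gene.chrom][s - 1 : e])
                    if gene.strand == "-":
                        piece = str(Seq(piece).reverse_complement())
                    chunks.append(piece)
                seq = "".join(chunks)
            elif mrna.id in fasta:
                seq = str(fasta[mrna.id][:])
            elif gene_id in fasta:
                seq = str(fasta[gene_id][:])
            else:
                warnings.warn(f"{gene_id}: no sequence in {fasta_path}; skipped")
                continue
            models.append(
                GeneModel(
                    gene_id=gene_id,
                    symbol=symbol,
                    chrom=gene.chrom,
                    strand=gene.strand,
                    cds_intervals=intervals,
                    coding_sequence=seq,
                )
            )
        except ValueError as exc:
            warnings.warn(f"{gene_id}: excluded ({exc})")
    return models


def write_gff(models: Sequence[GeneModel], path: str | Path) -> Path:
    """Write gene models as a GFF3 subset (gene/mRNA/CDS features)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(models, key=lambda m: (m.chrom, m.span[0])):
            start, end = min(s for s, _ in g.cds_intervals), max(
                e for _, e in g.cds_intervals
            )
            fh.write(
                f"{g.chrom}\tintroscan\tgene\t{start}\t{end}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id};Name={g.symbol}\n"
            )
            mrna_id = f"{g.gene_id}.t1"
            fh.write(
                f"{g.chrom}\tintroscan\tmRNA\t{start}\t{end}\t.\t{g.strand}\t.\t"
                f"ID={mrna_id};Parent={g.gene_id}\n"
            )
            for i, (s, e) in enumerate(sorted(g.cds_intervals)):
                fh.write(
                    f"{g.chrom}\tintroscan\tCDS\t{s}\t{e}\t.\t{g.strand}\t0\t"
                    f"ID={mrna_id}.cds{i};Parent={mrna_id}\n"
                )
    return path


def write_cds_fasta(models: Sequence[GeneModel], path: str | Path) -> Path:
    """Write per-transcript coding sequences (coding orientation)."""
    path = Path(path)
    with open(path, "w") as fh:
        for g in sorted(models, key=lambda m: (m.chrom, m.span[0])):
            fh.write(f">{g.gene_id}.t1\n")
            seq = g.coding_sequence
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")
    return path


# ---------------------------------------------------------------------------
# count matrices
# ---------------------------------------------------------------------------

@dataclass
class CountMatrix:
    """Gene × sample matrix of non-negative integer read counts."""

    counts: pd.DataFrame  # index: gene ids, columns: sample ids
    groups: pd.Series  # sample id -> group label

    def __post_init__(self) -> None:
        c = self.counts
        if not np.issubdtype(c.values.dtype, np.integer):
            if not np.allclose(c.values, np.round(c.values)):
                raise ValueError("counts must be integers")
            self.counts = c.astype(np.int64)
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        if list(self.groups.index) != list(self.counts.columns):
            raise ValueError("groups index must match count matrix columns")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]


def read_counts(path: str | Path) -> CountMatrix:
    """Read a TSV count table.

    Column headers are ``sample:group``; the first column holds gene ids.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.isna().any().any():
        raise FormatError(f"{path}: ragged or missing values in count table")
    samples, group_labels = [], []
    for col in df.columns:
        if ":" not in col:
            raise FormatError(f"{path}: column {col!r} lacks a ':group' suffix")
        s, g = col.rsplit(":", 1)
        samples.append(s)
        group_labels.append(g)
    vals = df.values
    if not np.allclose(vals, np.round(vals)) or (vals < 0).any():
        raise FormatError(f"{path}: counts must be non-negative integers")
    counts = pd.DataFrame(
        vals.astype(np.int64), index=df.index.astype(str), columns=samples
    )
    groups = pd.Series(group_labels, index=samples, name="group")
    return CountMatrix(counts=counts, groups=groups)


def write_counts(matrix: CountMatrix, path: str | Path) -> Path:
    path = Path(path)
    df = matrix.counts.copy()
    df.columns = [f"{s}:{matrix.groups[s]}" for s in matrix.counts.columns]
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t")
    return path
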