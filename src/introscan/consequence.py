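"""Transcript-consequence annotation of coding SNPs.

Maps a genomic substitution into a coding sequence (strand-aware), extracts
the affected codon, translates reference and alternate codons with the
standard nuclear genetic code, and classifies the change as synonymous,
missense, or nonsense.  SIFT substitution-tolerance scores, where supplied,
are classified with a single threshold: scores in [0, 0.05] are
"deleterious" (the boundary value is read as deleterious), scores above
0.05 up to 1 are "tolerated", absent scores are "unscored".
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Seq import Seq

from .io import GeneModel, VariantCall

SYNONYMOUS = "synonymous"
MISSENSE = "missense"
NONSENSE = "nonsense"

DELETERIOUS = "deleterious"
TOLERATED = "tolerated"
UNSCORED = "unscored"

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass(frozen=True)
class SiftThresholds:
    deleterious_max: float = 0.05

    def __post_init__(self) -> None:
        if not 0 < self.deleterious_max < 1:
            raise ValueError("deleterious_max must be in (0, 1)")


@dataclass(frozen=True)
class ConsequenceRecord:
    """One annotated coding substitution (the columns of a VEP-style report).

    ``cds_position`` is the 1-based offset in the coding sequence;
    ``protein_position`` = ceil(cds_position / 3).  ``codon_change`` shows
    the reference and alternate codons with the substituted base upper-case
    and the other two lower-case, e.g. ``"Aga/Gga"``.
    """

    gene_symbol: str
    allele: str  # alt base in coding orientation
    cds_position: int
    protein_position: int
    ref_aa: str
    alt_aa: str
    codon_change: str
    consequence_class: str
    sift_score: float | None = None
    sift_class: str = UNSCORED

    def __post_init__(self) -> None:
        if self.protein_position != (self.cds_position + 2) // 3:
            raise ValueError("protein_position inconsistent with cds_position")


def sift_classify(score: float | None, thresholds: SiftThresholds | None = None) -> str:
    """Classify a SIFT score: <= 0.05 deleterious, otherwise tolerated."""
    thresholds = thresholds or SiftThresholds()
    if score is None:
        return UNSCORED
    if not 0 <= score <= 1:
        raise ValueError(f"SIFT score {score} outside [0, 1]")
    return DELETERIOUS if score <= thresholds.deleterious_max else TOLERATED


def annotate(
    snp: VariantCall,
    gene: GeneModel,
    sift_score: float | None = None,
    thresholds: SiftThresholds | None = None,
) -> ConsequenceRecord:
    """Annotate a single-nucleotide substitution within a gene's CDS.

    The SNP's alleles are given on the genomic forward strand; for
    minus-strand genes they are complemented into coding orientation.
    Raises if the position lies outside the CDS or the VCF reference base
    disagrees with the coding sequence.
    """
    cds_pos = gene.genomic_to_cds(snp.pos)  # raises when outside CDS
    seq = gene.coding_sequence
    if gene.strand == "+":
        coding_ref, coding_alt = snp.ref.upper(), snp.alt.upper()
    else:
        coding_ref = snp.ref.upper().translate(_COMPLEMENT)
        coding_alt = snp.alt.upper().translate(_COMPLEMENT)
    expected_ref = seq[cds_pos - 1]
    if coding_ref != expected_ref:
        raise ValueError(
            f"{gene.gene_id} {snp.chrom}:{snp.pos}: VCF ref {snp.ref!r} "
            f"(coding {coding_ref!r}) does not match coding sequence base "
            f"{expected_ref!r} at CDS position {cds_pos}"
        )
    codon_idx = (cds_pos - 1) // 3
    slot = (cds_pos - 1) % 3
    ref_codon = seq[3 * codon_idx : 3 * codon_idx + 3]
    alt_codon = ref_codon[:slot] + coding_alt + ref_codon[slot + 1 :]
    ref_aa = str(Seq(ref_codon).translate())
    alt_aa = str(Seq(alt_codon).translate())
    if alt_aa == "*" and ref_aa != "*":
        klass = NONSENSE
    elif ref_aa == alt_aa:
        klass = SYNONYMOUS
    else:
        klass = MISSENSE

    def _fmt(codon: str) -> str:
        low = codon.lower()
        return low[:slot] + codon[slot].upper() + low[slot + 1 :]

    return ConsequenceRecord(
        gene_symbol=gene.symbol,
        allele=coding_alt,
        cds_position=cds_pos,
        protein_position=codon_idx + 1,
        ref_aa=ref_aa,
        alt_aa=alt_aa,
        codon_change=f"{_fmt(ref_codon)}/{_fmt(alt_codon)}",
        consequence_class=klass,
        sift_score=sift_score,
        sift_class=sift_classify(sift_score, thresholds),
    )
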