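"""Candidate-gene assembly: polymorphic-in-locus ∪ DE-in-locus.

Two independent lines of evidence nominate a gene: carrying at least one
missense candidate SNP inside a detected introgressed segment, or being
differentially expressed with its gene body overlapping a segment.  The
report makes the overlap between the two classes explicit — in the study
design this pipeline emulates, the overlap is typically empty, which is
itself an informative observation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .consequence import MISSENSE, ConsequenceRecord
from .io import GeneModel
from .segments import IntrogressedSegment


@dataclass
class CandidateSet:
    """Nominated candidate genes for one congenic strain."""

    strain: str
    polymorphic_candidates: list[str]
    de_in_locus_candidates: list[str]
    evidence: pd.DataFrame  # gene, evidence class, detail

    @property
    def overlap(self) -> list[str]:
        return sorted(set(self.polymorphic_candidates) & set(self.de_in_locus_candidates))

    @property
    def union(self) -> list[str]:
        return sorted(set(self.polymorphic_candidates) | set(self.de_in_locus_candidates))


def _overlaps(a_start: int, a_end: int, b_start: int, b_end: int) -> bool:
    return a_start < b_end and b_start < a_end


def _contained(a_start: int, a_end: int, b_start: int, b_end: int) -> bool:
    return b_start <= a_start and a_end <= b_end


def cross_reference(
    de_genes: Iterable[str],
    segments: Sequence[IntrogressedSegment],
    gene_models: Sequence[GeneModel],
    mode: str = "any_overlap",
) -> list[str]:
    """DE genes whose gene body lies within an introgressed segment.

    ``mode="any_overlap"`` (default) includes a gene when its genomic span
    intersects any segment; ``mode="containment"`` requires the full gene
    body inside a segment.  DE genes without a gene model are skipped with
    a warning.
    """
    if mode not in ("any_overlap", "containment"):
        raise ValueError("mode must be 'any_overlap' or 'containment'")
    test = _overlaps if mode == "any_overlap" else _contained
    by_id = {g.gene_id: g for g in gene_models}
    by_symbol = {g.symbol: g for g in gene_models}
    hits: list[str] = []
    for gene in de_genes:
        model = by_id.get(gene) or by_symbol.get(gene)
        if model is None:
            warnings.warn(f"{gene}: no gene model with coordinates; skipped")
            continue
        start, end = model.span
        if any(
            seg.chrom == model.chrom and test(start, end, seg.start, seg.end)
            for seg in segments
        ):
            hits.append(gene)
    return sorted(hits)


def nominate(
    records: Sequence[ConsequenceRecord],
    de_in_locus: Iterable[str],
    strain: str,
    gene_models: Sequence[GeneModel] | None = None,
) -> CandidateSet:
    """Assemble the candidate set for one congenic strain.

    ``records`` are consequence annotations of candidate SNPs already
    restricted to detected segments; only missense records nominate a gene
    (synonymous changes carry no protein-level evidence and stop gains are
    reported separately).  Gene ordering in the report is deterministic:
    by chromosome and gene start when models are supplied, else by name.
    """
    polymorphic = sorted({r.gene_symbol for r in records if r.consequence_class == MISSENSE})
    de_genes = sorted(set(de_in_locus))
    if gene_models:
        order = {
            g.symbol: (g.chrom, g.span[0]) for g in gene_models
        }
        keyfn = lambda g: order.get(g, ("~", 0)) + (g,)
        polymorphic = sorted(polymorphic, key=keyfn)
        de_genes = sorted(de_genes, key=keyfn)
    rows = []
    for r in records:
        if r.consequence_class == MISSENSE:
            rows.append(
                (r.gene_symbol, "polymorphic_in_locus",
                 f"{r.codon_change} {r.ref_aa}{r.protein_position}{r.alt_aa} "
                 f"[{r.sift_class}]")
            )
    for g in de_genes:
        rows.append((g, "de_in_locus", "differentially expressed within segment"))
    evidence = pd.DataFrame(rows, columns=["gene", "evidence", "detail"])
    return CandidateSet(
        strain=strain,
        polymorphic_candidates=list(polymorphic),
        de_in_locus_candidates=list(de_genes),
        evidence=evidence,
    )


def write_report(candidates: CandidateSet, tsv_path: str | Path, text_path: str | Path | None = None) -> Path:
    """Write the candidate report as TSV (and optionally human-readable text)."""
    tsv_path = Path(tsv_path)
    candidates.evidence.to_csv(tsv_path, sep="\t", index=False)
    if text_path is not None:
        n_poly = len(candidates.polymorphic_candidates)
        n_de = len(candidates.de_in_locus_candidates)
        n_ov = len(candidates.overlap)
        lines = [
            f"Candidate genes for strain {candidates.strain}",
            "=" * 50,
            f"polymorphic in locus : {n_poly} gene(s)",
            f"  {', '.join(candidates.polymorphic_candidates) or '(none)'}",
            f"DE within locus      : {n_de} gene(s)",
            f"  {', '.join(candidates.de_in_locus_candidates) or '(none)'}",
            f"overlap              : {n_ov} gene(s)"
            + (f" — {', '.join(candidates.overlap)}" if n_ov else ""),
            f"union                : {len(candidates.union)} gene(s)",
            "",
        ]
        Path(text_path).write_text("\n".join(lines))
    return tsv_path
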