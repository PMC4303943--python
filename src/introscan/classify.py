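"""Strain-of-origin labelling of coding SNP sites.

The genetic evidence is three quality-filtered variant tables: the donor
strain, the recipient strain, and a congenic strain derived from them.  A
site whose alt allele is seen in exactly one parent is strain-informative;
the allele carried by the congenic animal at such sites reveals the local
ancestry of its chromosome.

Absence handling: RNA-Seq only shows expressed positions, so a missing
record in the congenic table is evidence of the reference allele only when
the site is independently known to be covered (the ``covered_ref`` table).
Raw absence is left uninformative — this avoids phantom recipient segments
in unexpressed regions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import StrainVariantTable

logger = logging.getLogger(__name__)

DONOR_INFORMATIVE = "donor_informative"
RECIPIENT_INFORMATIVE = "recipient_informative"
UNINFORMATIVE = "uninformative"

ORIGIN_COLUMNS = ["chrom", "pos", "ref", "alt", "site_class", "origin"]


@dataclass
class SitePartition:
    """Three-way partition of parental SNP sites by allele specificity.

    Each DataFrame has columns chrom, pos, ref, alt; ``alt`` is the
    strain-specific (or shared) alt allele at the site.
    """

    donor_specific: pd.DataFrame
    recipient_specific: pd.DataFrame
    shared: pd.DataFrame
    n_discarded: int = 0


def strain_specific_sites(
    donor: StrainVariantTable, recipient: StrainVariantTable
) -> SitePartition:
    """Partition alt alleles into donor-specific, recipient-specific, shared.

    An alt allele is donor-specific iff it appears in the donor table and
    not in the recipient table at the same site (and symmetrically).  Sites
    at which the two tables disagree on the reference allele are discarded
    with a warning (reference inconsistency).
    """
    d = donor.variants[["chrom", "pos", "ref", "alt"]].drop_duplicates()
    r = recipient.variants[["chrom", "pos", "ref", "alt"]].drop_duplicates()

    # reference consistency per (chrom, pos)
    refs = pd.concat([d[["chrom", "pos", "ref"]], r[["chrom", "pos", "ref"]]])
    nref = refs.drop_duplicates().groupby(["chrom", "pos"]).size()
    bad = set(nref[nref > 1].index)
    if bad:
        logger.warning("discarding %d sites with conflicting ref alleles", len(bad))
        d = d[~d.set_index(["chrom", "pos"]).index.isin(bad)]
        r = r[~r.set_index(["chrom", "pos"]).index.isin(bad)]

    merged = d.merge(r, on=["chrom", "pos", "ref", "alt"], how="outer", indicator=True)
    donor_specific = merged[merged._merge == "left_only"].drop(columns="_merge")
    recipient_specific = merged[merged._merge == "right_only"].drop(columns="_merge")
    shared = merged[merged._merge == "both"].drop(columns="_merge")
    sort = lambda x: x.sort_values(["chrom", "pos", "alt"], kind="mergesort").reset_index(drop=True)
    return SitePartition(
        donor_specific=sort(donor_specific),
        recipient_specific=sort(recipient_specific),
        shared=sort(shared),
        n_discarded=len(bad),
    )


def classify_congenic_origin(
    congenic: StrainVariantTable,
    partition: SitePartition,
    covered_ref: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Label every strain-informative site by the congenic animal's ancestry.

    At a donor-specific site: the congenic table carrying the donor alt →
    donor_informative; the site covered at the reference allele →
    recipient_informative; otherwise uninformative.  Recipient-specific
    sites follow the converse logic.  ``covered_ref`` holds (chrom, pos) of
    congenic sites observed to agree with the reference.

    Returns a DataFrame with ORIGIN_COLUMNS; every input site receives
    exactly one label.
    """
    cong_alts = congenic.key_set()
    covered = (
        set(zip(covered_ref.chrom, covered_ref.pos))
        if covered_ref is not None and len(covered_ref)
        else set()
    )

    def _classify(df: pd.DataFrame, site_class: str, match_label: str, absent_label: str):
        rows = []
        for row in df.itertuples(index=False):
            if (row.chrom, row.pos, row.alt) in cong_alts:
                origin = match_label
            elif (row.chrom, row.pos) in covered:
                origin = absent_label
            else:
                origin = UNINFORMATIVE
            rows.append((row.chrom, row.pos, row.ref, row.alt, site_class, origin))
        return rows

    rows = _classify(
        partition.donor_specific, "donor_specific",
        DONOR_INFORMATIVE, RECIPIENT_INFORMATIVE,
    )
    rows += _classify(
        partition.recipient_specific, "recipient_specific",
        RECIPIENT_INFORMATIVE, DONOR_INFORMATIVE,
    )
    calls = pd.DataFrame(rows, columns=ORIGIN_COLUMNS)
    return calls.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)


def candidate_snp_filter(
    donor: StrainVariantTable,
    recipient: StrainVariantTable,
    congenic: StrainVariantTable,
    loci: list[tuple[str, int, int]],
) -> pd.DataFrame:
    """SNPs possibly associated with the donor phenotype.

    Returns variants inside a congenic locus whose alt allele is present in
    both the donor and the congenic strain but absent from the recipient
    (the control).  ``loci`` are (chrom, start, end) 0-based half-open bp
    intervals, typically detected introgressed segments.
    """
    if not loci:
        logger.warning("candidate_snp_filter: no loci supplied; empty result")
        return pd.DataFrame(columns=["chrom", "pos", "ref", "alt"])
    shared_dc = donor.variants.merge(
        congenic.variants[["chrom", "pos", "ref", "alt"]],
        on=["chrom", "pos", "ref", "alt"],
    )[["chrom", "pos", "ref", "alt"]].drop_duplicates()
    rec_keys = recipient.key_set()
    keep_allele = [
        (row.chrom, row.pos, row.alt) not in rec_keys
        for row in shared_dc.itertuples(index=False)
    ]
    shared_dc = shared_dc[np.asarray(keep_allele, dtype=bool)]
    in_locus = [
        any(c == row.chrom and s < row.pos <= e for c, s, e in loci)
        for row in shared_dc.itertuples(index=False)
    ]
    out = shared_dc[np.asarray(in_locus, dtype=bool)]
    return out.sort_values(["chrom", "pos", "alt"], kind="mergesort").reset_index(drop=True)
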