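"""Binned informative-SNP counts and introgressed-segment delimitation.

Donor segments are delimited from binned origin calls with a transparent
threshold-plus-run-merging rule: a bin is donor-labelled when it has enough
donor-informative support and a high enough donor fraction; runs of donor
bins are merged across short gaps that carry no recipient evidence
(expression deserts are tolerated rather than read as recipient origin).
Boundaries are reported at bin resolution by default.

The breeding arithmetic lives here too: after N marker-selected backcrosses
the donor segment flanking the selected marker is expected to be 100/N cM
per side, converted to bp at a uniform rate (default 2 Mb/cM).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classify import DONOR_INFORMATIVE, RECIPIENT_INFORMATIVE
from .simulate import BreedingModel

FOCAL_BIN_WIDTH = 1_000_000
GENOME_BIN_WIDTH = 10_000_000


@dataclass
class BinnedCounts:
    """Per-bin informative-SNP counts on one chromosome.

    Bins are 0-based half-open [k*w, (k+1)*w); a call at 1-based position p
    falls in bin p // w (a position exactly on a boundary belongs to the
    right-open bin starting there).
    """

    chrom: str
    bin_width: int
    donor: np.ndarray
    recipient: np.ndarray

    @property
    def n_bins(self) -> int:
        return len(self.donor)

    def bin_interval(self, i: int) -> tuple[int, int]:
        return i * self.bin_width, (i + 1) * self.bin_width

    def to_frame(self) -> pd.DataFrame:
        starts = np.arange(self.n_bins) * self.bin_width
        return pd.DataFrame(
            {
                "chrom": self.chrom,
                "start": starts,
                "end": starts + self.bin_width,
                "donor": self.donor,
                "recipient": self.recipient,
            }
        )


@dataclass(frozen=True)
class IntrogressedSegment:
    """A delimited donor-origin interval (bp, 0-based half-open)."""

    chrom: str
    start: int
    end: int
    n_donor_snps: int
    n_recipient_snps: int
    origin: str = "donor"

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("segment end must exceed start")

    @property
    def length_mbp(self) -> float:
        return (self.end - self.start) / 1e6


@dataclass(frozen=True)
class FlankingExpectation:
    """Expected residual donor DNA flanking a selected marker."""

    n_backcrosses: int
    per_side_cM: float
    total_cM: float
    per_side_bp: float


def bin_origin_calls(
    calls: pd.DataFrame,
    bin_width: int = FOCAL_BIN_WIDTH,
    chrom: str | None = None,
    chrom_length: int | None = None,
) -> BinnedCounts:
    """Tally donor-/recipient-informative calls into fixed-width bins."""
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if chrom is None:
        chroms = calls["chrom"].unique()
        if len(chroms) != 1:
            raise ValueError("calls span several chromosomes; pass chrom=")
        chrom = chroms[0]
    sub = calls[calls["chrom"] == chrom]
    informative = sub[sub["origin"].isin([DONOR_INFORMATIVE, RECIPIENT_INFORMATIVE])]
    max_pos = int(informative["pos"].max()) if len(informative) else 0
    extent = max(chrom_length or 0, max_pos + 1)
    n_bins = max(1, int(np.ceil(extent / bin_width)))
    donor = np.zeros(n_bins, dtype=np.int64)
    recipient = np.zeros(n_bins, dtype=np.int64)
    for origin, arr in ((DONOR_INFORMATIVE, donor), (RECIPIENT_INFORMATIVE, recipient)):
        pos = informative.loc[informative["origin"] == origin, "pos"].to_numpy(
            dtype=np.int64
        )
        idx = pos // bin_width
        np.add.at(arr, idx, 1)
    return BinnedCounts(chrom=chrom, bin_width=bin_width, donor=donor, recipient=recipient)


def detect_segments(
    bins: BinnedCounts,
    min_support: int = 3,
    donor_fraction: float = 0.8,
    max_gap_bins: int = 2,
) -> list[IntrogressedSegment]:
    """Delimit donor-origin segments from binned counts.

    A bin is donor-labelled iff its donor count is >= ``min_support`` and
    donor/(donor+recipient) >= ``donor_fraction``.  Runs of donor bins are
    merged across gaps of at most ``max_gap_bins`` bins carrying no
    recipient-informative SNPs (so sparse donor evidence below threshold,
    or none at all, does not split a segment).  Boundaries are the outer
    edges of the terminal donor bins.
    """
    d, r = bins.donor, bins.recipient
    total = d + r
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(total > 0, d / np.maximum(total, 1), 0.0)
    is_donor = (d >= min_support) & (frac >= donor_fraction)
    bridgeable = (~is_donor) & (r == 0)

    segments: list[IntrogressedSegment] = []
    donor_bins = np.flatnonzero(is_donor)
    if len(donor_bins) == 0:
        return segments
    run_start = donor_bins[0]
    prev = donor_bins[0]
    for b in donor_bins[1:]:
        gap = np.arange(prev + 1, b)
        if len(gap) <= max_gap_bins and bridgeable[gap].all():
            prev = b
            continue
        segments.append(_make_segment(bins, run_start, prev))
        run_start = prev = b
    segments.append(_make_segment(bins, run_start, prev))
    return segments


def _make_segment(bins: BinnedCounts, first_bin: int, last_bin: int) -> IntrogressedSegment:
    start = first_bin * bins.bin_width
    end = (last_bin + 1) * bins.bin_width
    sl = slice(first_bin, last_bin + 1)
    return IntrogressedSegment(
        chrom=bins.chrom,
        start=start,
        end=end,
        n_donor_snps=int(bins.donor[sl].sum()),
        n_recipient_snps=int(bins.recipient[sl].sum()),
    )


def cumulative_length(segments) -> float:
    """Total length in Mbp of non-overlapping segments.

    Accepts :class:`IntrogressedSegment` objects or plain (start, end) /
    (chrom, start, end) tuples in bp.
    """
    ivs = []
    for seg in segments:
        if isinstance(seg, IntrogressedSegment):
            ivs.append((seg.chrom, seg.start, seg.end))
        elif len(seg) == 3:
            ivs.append(tuple(seg))
        else:
            ivs.append(("", seg[0], seg[1]))
    ivs.sort()
    for (c1, s1, e1), (c2, s2, e2) in zip(ivs, ivs[1:]):
        if c1 == c2 and s2 < e1:
            raise ValueError(f"overlapping segments: [{s1},{e1}) and [{s2},{e2})")
    return sum(e - s for _, s, e in ivs) / 1e6


def expected_flanking(model: BreedingModel) -> FlankingExpectation:
    """Closed-form expected flanking donor length: 100/N cM per side."""
    n = model.n_backcrosses
    if n < 1:
        raise ValueError("n_backcrosses must be >= 1")
    per_side = 100.0 / n
    return FlankingExpectation(
        n_backcrosses=n,
        per_side_cM=per_side,
        total_cM=2 * per_side,
        per_side_bp=per_side * model.bp_per_cM,
    )


def plot_binned_counts(bins: BinnedCounts, segments=None, ax=None):
    """Mirror-plot of binned informative SNPs: donor counts up (blue),
    recipient counts down (red), detected segments shaded."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(10, 3))
    mid = (np.arange(bins.n_bins) + 0.5) * bins.bin_width / 1e6
    w = bins.bin_width / 1e6
    ax.bar(mid, bins.donor, width=w, color="tab:blue", label="donor-informative")
    ax.bar(mid, -bins.recipient, width=w, color="tab:red", label="recipient-informative")
    for seg in segments or []:
        ax.axvspan(seg.start / 1e6, seg.end / 1e6, color="tab:blue", alpha=0.15)
    ax.axhline(0, color="black", lw=0.5)
    ax.set_xlabel(f"{bins.chrom} position (Mbp)")
    ax.set_ylabel(f"coding SNPs / {bins.bin_width // 10**6} Mbp")
    ax.legend(loc="upper right", fontsize=8)
    return ax


def genome_scan(
    calls: pd.DataFrame,
    chrom_lengths: dict[str, int] | None = None,
    bin_width: int = GENOME_BIN_WIDTH,
    **detect_kwargs,
) -> dict[str, list[IntrogressedSegment]]:
    """Detect donor segments on every chromosome present in ``calls`` (or
    listed in ``chrom_lengths``); chromosomes without segments map to []."""
    chroms = sorted(chrom_lengths) if chrom_lengths else sorted(calls["chrom"].unique())
    report: dict[str, list[IntrogressedSegment]] = {}
    for chrom in chroms:
        length = chrom_lengths.get(chrom) if chrom_lengths else None
        binned = bin_origin_calls(
            calls, bin_width=bin_width, chrom=chrom, chrom_length=length
        )
        report[chrom] = detect_segments(binned, **detect_kwargs)
    return report
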