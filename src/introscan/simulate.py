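"""Synthetic inputs with known ground truth for every pipeline stage.

The generator emulates the study design the pipeline was built for: two
divergent inbred parental genomes (a disease "donor" and a healthy
"recipient"), a congenic genome produced by repeated marker-selected
backcrossing of the donor locus into the recipient background, RNA-Seq
variant observation that only sees expressed coding positions (coverage
dropout) and occasionally miscalls an allele, and negative-binomial count
matrices with designated differentially expressed genes.

Inbred parents are homozygous, so each chromosome of the congenic animal is
tracked as a single haploid mosaic of donor/recipient intervals; the F1
starting point is a whole-chromosome donor haplotype paired with a
recipient homolog.  Crossovers follow the Haldane (no-interference) model:
a Poisson number of exchanges per meiosis with mean equal to the map length
in Morgans, breakpoints uniform on the genetic map.  Genetic and physical
coordinates are interconverted at a uniform rate (default 2 Mb/cM).
"""

from __future__ import annotations

import math
from bisect import bisect_right
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .io import CountMatrix, GeneModel, StrainVariantTable, VariantCall

DONOR = "donor"
RECIPIENT = "recipient"

_CODONS = np.array(
    [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"], dtype=object
)
_STOP = {"TAA", "TAG", "TGA"}
_SENSE_CODONS = np.array([c for c in _CODONS if c not in _STOP], dtype=object)
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


# ---------------------------------------------------------------------------
# specifications
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomeSpec:
    """Layout of the simulated genome and its coding divergence.

    ``snp_density`` is the expected number of donor-vs-recipient divergent
    coding sites per Mbp of chromosome; sites are placed uniformly within
    the simulated CDS.
    """

    chromosomes: tuple[tuple[str, int], ...] = (("chr1", 290_000_000),)
    coding_fraction: float = 0.02
    snp_density: float = 15.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name, length in self.chromosomes:
            if length <= 0:
                raise ValueError(f"chromosome {name} has non-positive length")
        if not 0 < self.coding_fraction <= 1:
            raise ValueError("coding_fraction must be in (0, 1]")
        if self.snp_density < 0:
            raise ValueError("snp_density must be >= 0")


@dataclass(frozen=True)
class BreedingModel:
    """Marker-assisted backcross design.

    ``genetic_lengths`` maps chromosome name to map length in cM; if omitted
    it is derived from ``chrom_lengths_bp`` via ``bp_per_cM``.
    ``selected_markers`` maps chromosome name to the bp positions whose donor
    allele is retained at every generation; chromosomes without markers
    segregate freely.
    """

    n_backcrosses: int = 8
    bp_per_cM: float = 2_000_000.0
    chrom_lengths_bp: tuple[tuple[str, int], ...] = (("chr1", 290_000_000),)
    selected_markers: tuple[tuple[str, tuple[int, ...]], ...] = (
        ("chr1", (150_000_000,)),
    )
    crossover_model: str = "haldane"

    def __post_init__(self) -> None:
        if self.n_backcrosses < 1:
            raise ValueError("n_backcrosses must be >= 1")
        if self.bp_per_cM <= 0:
            raise ValueError("bp_per_cM must be positive")
        if self.crossover_model != "haldane":
            raise ValueError("only the 'haldane' crossover model is implemented")
        lengths = dict(self.chrom_lengths_bp)
        for chrom, markers in self.selected_markers:
            if chrom not in lengths:
                raise ValueError(f"markers given for unknown chromosome {chrom}")
            for m in markers:
                if not 0 < m <= lengths[chrom]:
                    raise ValueError(
                        f"selected marker {chrom}:{m} outside chromosome"
                    )

    def genetic_length_cM(self, chrom: str) -> float:
        return dict(self.chrom_lengths_bp)[chrom] / self.bp_per_cM

    def markers_cM(self, chrom: str) -> list[float]:
        d = dict(self.selected_markers)
        return [m / self.bp_per_cM for m in d.get(chrom, ())]


@dataclass(frozen=True)
class ObservationModel:
    """RNA-Seq visibility of coding variants.

    ``coverage_dropout`` models unexpressed/low-coverage sites;
    ``error_rate`` is the probability a covered site is reported with the
    wrong allele (ref miscalled as alt or vice versa).  QUAL values of true
    calls are uniform on [true_qual_min, true_qual_max] (all pass the
    default QUAL>=100 filter); erroneous calls draw QUAL uniform on
    [error_qual_min, error_qual_max], so the filter removes some but not
    all of them.
    """

    coverage_dropout: float = 0.2
    error_rate: float = 0.005
    true_qual_min: float = 100.0
    true_qual_max: float = 255.0
    error_qual_min: float = 30.0
    error_qual_max: float = 150.0

    def __post_init__(self) -> None:
        for p in (self.coverage_dropout, self.error_rate):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must be in [0, 1]")


@dataclass(frozen=True)
class CountSimSpec:
    """Negative-binomial count-matrix simulation."""

    n_genes: int = 2000
    n_samples_per_group: int = 3
    nb_mean_range: tuple[float, float] = (20.0, 2000.0)
    nb_dispersion: float = 0.1
    de_fraction: float = 0.1
    de_log2fc_values: tuple[float, ...] = (-2.0, -1.0, 1.0, 2.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.nb_dispersion <= 0:
            raise ValueError("dispersion must be positive")
        if not 0 <= self.de_fraction <= 1:
            raise ValueError("de_fraction must be in [0, 1]")


# ---------------------------------------------------------------------------
# genome mosaic
# ---------------------------------------------------------------------------

@dataclass
class GenomeMosaic:
    """Per-chromosome donor/recipient tiling, 0-based half-open bp intervals."""

    intervals: dict[str, list[tuple[int, int, str]]]

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for chrom, ivs in self.intervals.items():
            if not ivs:
                raise ValueError(f"{chrom}: empty mosaic")
            if ivs[0][0] != 0:
                raise ValueError(f"{chrom}: mosaic does not start at 0")
            for (s1, e1, o1), (s2, e2, o2) in zip(ivs, ivs[1:]):
                if e1 != s2:
                    raise ValueError(f"{chrom}: gap/overlap at {e1}->{s2}")
                if o1 == o2:
                    raise ValueError(f"{chrom}: adjacent intervals share origin")
            for s, e, o in ivs:
                if e <= s:
                    raise ValueError(f"{chrom}: empty interval [{s},{e})")
                if o not in (DONOR, RECIPIENT):
                    raise ValueError(f"{chrom}: unknown origin {o!r}")

    @classmethod
    def from_segments(
        cls,
        chrom_lengths: dict[str, int],
        donor_segments: dict[str, list[tuple[int, int]]],
    ) -> "GenomeMosaic":
        """Build a fixed-truth mosaic from donor segments (bp, half-open)."""
        intervals: dict[str, list[tuple[int, int, str]]] = {}
        for chrom, length in chrom_lengths.items():
            segs = sorted(donor_segments.get(chrom, []))
            ivs: list[tuple[int, int, str]] = []
            cursor = 0
            for s, e in segs:
                if not 0 <= s < e <= length:
                    raise ValueError(f"segment [{s},{e}) outside {chrom}")
                if s < cursor:
                    raise ValueError("donor segments overlap")
                if s > cursor:
                    ivs.append((cursor, s, RECIPIENT))
                ivs.append((s, e, DONOR))
                cursor = e
            if cursor < length:
                ivs.append((cursor, length, RECIPIENT))
            intervals[chrom] = ivs
        return cls(intervals=intervals)

    def origin_at(self, chrom: str, pos_1based: int) -> str:
        pos0 = pos_1based - 1
        ivs = self.intervals[chrom]
        starts = [s for s, _, _ in ivs]
        i = bisect_right(starts, pos0) - 1
        s, e, origin = ivs[i]
        if not s <= pos0 < e:
            raise ValueError(f"{chrom}:{pos_1based} outside mosaic")
        return origin

    def origins_at(self, chrom: str, pos_1based: np.ndarray) -> np.ndarray:
        """Vectorized origin lookup; returns a boolean array (True = donor)."""
        ivs = self.intervals[chrom]
        starts = np.array([s for s, _, _ in ivs])
        donor_flags = np.array([o == DONOR for _, _, o in ivs])
        idx = np.searchsorted(starts, np.asarray(pos_1based) - 1, side="right") - 1
        return donor_flags[idx]

    def donor_fraction(self, chrom: str) -> float:
        ivs = self.intervals[chrom]
        total = ivs[-1][1]
        donor = sum(e - s for s, e, o in ivs if o == DONOR)
        return donor / total

    def donor_segments(self, chrom: str) -> list[tuple[int, int]]:
        return [(s, e) for s, e, o in self.intervals[chrom] if o == DONOR]


# ---------------------------------------------------------------------------
# parental genomes
# ---------------------------------------------------------------------------

@dataclass
class ParentalGenomes:
    """Truth output of :func:`simulate_parental_genomes`.

    ``sites`` columns: chrom, pos (1-based), ref, alt, carrier
    (donor|recipient), donor_allele, recipient_allele.
    """

    sites: pd.DataFrame
    gene_models: list[GeneModel]

    def truth_table(self, strain: str) -> pd.DataFrame:
        """Variant truth set (sites where ``strain`` differs from reference)."""
        if strain not in (DONOR, RECIPIENT):
            raise ValueError(strain)
        s = self.sites
        return s[s.carrier == strain].reset_index(drop=True)


_ALT_BASES = {b: [x for x in "ACGT" if x != b] for b in "ACGT"}


def _random_coding_sequence(n_codons: int, rng: np.random.Generator) -> str:
    codons = _SENSE_CODONS[rng.integers(0, len(_SENSE_CODONS), size=n_codons)]
    body = "".join(codons)
    return "ATG" + body[3:]


def simulate_parental_genomes(spec: GenomeSpec) -> ParentalGenomes:
    """Simulate two divergent inbred parents and their shared gene models.

    Gene models (GFF3-style CDS plus coding sequence) are laid down to cover
    ``coding_fraction`` of each chromosome; divergent coding sites are then
    placed uniformly within the CDS at ``snp_density`` expected sites per
    Mbp of chromosome.  At each site one parent (chosen with probability
    1/2) carries a non-reference allele and the other matches the reference.
    """
    rng = np.random.default_rng(spec.seed)
    gene_models: list[GeneModel] = []
    rows: list[tuple] = []
    gene_counter = 0
    for chrom, length in spec.chromosomes:
        # --- place genes ---
        mean_cds = 1200  # bp
        mean_gap = mean_cds * (1 - spec.coding_fraction) / spec.coding_fraction
        genes_here: list[GeneModel] = []
        pos = int(rng.exponential(mean_gap)) + 1
        while True:
            n_codons = int(rng.integers(100, 700))
            cds_len = 3 * n_codons
            intron = int(rng.integers(100, 2000)) if rng.random() < 0.3 else 0
            span = cds_len + intron
            if pos + span - 1 > length:
                break
            strand = "+" if rng.random() < 0.5 else "-"
            seq = _random_coding_sequence(n_codons, rng)
            if intron:
                cut = 3 * int(rng.integers(1, n_codons))
                iv = [(pos, pos + cut - 1), (pos + cut + intron, pos + span - 1)]
            else:
                iv = [(pos, pos + cds_len - 1)]
            intervals = iv if strand == "+" else iv[::-1]
            gene_counter += 1
            genes_here.append(
                GeneModel(
                    gene_id=f"G{gene_counter:06d}",
                    symbol=f"G{gene_counter:06d}",
                    chrom=chrom,
                    strand=strand,
                    cds_intervals=intervals,
                    coding_sequence=seq,
                )
            )
            pos += span + max(1, int(rng.exponential(mean_gap)))
        gene_models.extend(genes_here)

        # --- place divergent sites within CDS ---
        if spec.snp_density == 0 or not genes_here:
            continue
        coding_pos: list[np.ndarray] = []
        gene_idx: list[np.ndarray] = []
        for gi, g in enumerate(genes_here):  # genes laid down left to right
            for s, e in sorted(g.cds_intervals):
                coding_pos.append(np.arange(s, e + 1))
                gene_idx.append(np.full(e - s + 1, gi))
        coding_pos = np.concatenate(coding_pos)
        gene_idx = np.concatenate(gene_idx)
        n_sites = rng.poisson(spec.snp_density * length / 1e6)
        n_sites = min(n_sites, len(coding_pos))
        # with-replacement draw plus dedup: collisions are negligibly rare
        # at realistic densities and keep this O(n_sites)
        chosen = np.unique(rng.integers(0, len(coding_pos), size=n_sites))
        carriers = rng.random(len(chosen)) < 0.5
        alt_picks = rng.integers(0, 3, size=len(chosen))
        for k, ci in enumerate(chosen):
            gpos = int(coding_pos[ci])
            g = genes_here[gene_idx[ci]]
            cds_pos = g.genomic_to_cds(gpos)
            coding_ref = g.coding_sequence[cds_pos - 1]
            ref = coding_ref if g.strand == "+" else coding_ref.translate(_COMPLEMENT)
            alt = _ALT_BASES[ref][alt_picks[k]]
            carrier = DONOR if carriers[k] else RECIPIENT
            rows.append(
                (
                    chrom,
                    gpos,
                    ref,
                    alt,
                    carrier,
                    alt if carrier == DONOR else ref,
                    alt if carrier == RECIPIENT else ref,
                )
            )
    sites = pd.DataFrame(
        rows,
        columns=[
            "chrom", "pos", "ref", "alt", "carrier",
            "donor_allele", "recipient_allele",
        ],
    )
    return ParentalGenomes(sites=sites, gene_models=gene_models)


# ---------------------------------------------------------------------------
# backcross simulation
# ---------------------------------------------------------------------------

def _meiosis_cM(
    hap: list[tuple[float, float, str]],
    length_cM: float,
    rng: np.random.Generator,
) -> list[tuple[float, float, str]]:
    """One gamete from a parent carrying ``hap`` and a recipient homolog."""
    k = rng.poisson(length_cM / 100.0)
    breaks = np.sort(rng.uniform(0.0, length_cM, size=k))
    bounds = [0.0, *breaks.tolist(), length_cM]
    phase = int(rng.integers(2))  # 0 -> read from hap, 1 -> recipient homolog
    gamete: list[tuple[float, float, str]] = []
    for i in range(len(bounds) - 1):
        lo, hi = bounds[i], bounds[i + 1]
        if hi <= lo:
            continue
        if (phase + i) % 2 == 1:
            _extend(gamete, lo, hi, RECIPIENT)
        else:
            for s, e, o in hap:
                a, b = max(s, lo), min(e, hi)
                if b > a:
                    _extend(gamete, a, b, o)
    return gamete


def _extend(acc: list, start: float, end: float, origin: str) -> None:
    if acc and acc[-1][2] == origin and acc[-1][1] == start:
        acc[-1] = (acc[-1][0], end, origin)
    else:
        acc.append((start, end, origin))


def _origin_at_cM(hap: list[tuple[float, float, str]], x: float) -> str:
    for s, e, o in hap:
        if s <= x < e or (x == e == hap[-1][1]):
            return o
    raise AssertionError("position outside haplotype")


def simulate_backcross_chrom_cM(
    length_cM: float,
    markers_cM: Sequence[float],
    n_backcrosses: int,
    rng: np.random.Generator,
    max_tries: int = 100_000,
) -> list[tuple[float, float, str]]:
    """N generations of marker-selected backcrossing on one chromosome (cM).

    Starts from the F1 donor haplotype; at each generation the gamete
    retained is one carrying the donor allele at every selected marker
    (rejection sampling over meioses — the marker-assisted selection among
    offspring).  Chromosomes without markers accept any gamete.
    """
    hap: list[tuple[float, float, str]] = [(0.0, length_cM, DONOR)]
    for _ in range(n_backcrosses):
        for attempt in range(max_tries):
            gamete = _meiosis_cM(hap, length_cM, rng)
            if all(_origin_at_cM(gamete, m) == DONOR for m in markers_cM):
                hap = gamete
                break
        else:
            raise RuntimeError("no marker-carrying gamete found")
    return hap


def simulate_backcross(model: BreedingModel, seed: int | np.random.Generator) -> GenomeMosaic:
    """Simulate the congenic genome after N marker-selected backcrosses."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    intervals: dict[str, list[tuple[int, int, str]]] = {}
    for chrom, length_bp in model.chrom_lengths_bp:
        length_cM = model.genetic_length_cM(chrom)
        hap = simulate_backcross_chrom_cM(
            length_cM, model.markers_cM(chrom), model.n_backcrosses, rng
        )
        ivs: list[tuple[int, int, str]] = []
        cursor = 0
        for s, e, o in hap:
            end_bp = length_bp if e >= length_cM else int(round(e * model.bp_per_cM))
            end_bp = min(max(end_bp, cursor), length_bp)
            if end_bp > cursor:
                if ivs and ivs[-1][2] == o:
                    ivs[-1] = (ivs[-1][0], end_bp, o)
                else:
                    ivs.append((cursor, end_bp, o))
                cursor = end_bp
        if cursor < length_bp:  # numeric tail
            o = hap[-1][2]
            if ivs and ivs[-1][2] == o:
                ivs[-1] = (ivs[-1][0], length_bp, o)
            else:
                ivs.append((cursor, length_bp, o))
        intervals[chrom] = ivs
    return GenomeMosaic(intervals=intervals)


def flanking_lengths_cM(
    hap: list[tuple[float, float, str]], marker_cM: float
) -> tuple[float, float]:
    """(left, right) donor flank lengths around a selected marker, in cM."""
    for s, e, o in hap:
        if s <= marker_cM < e:
            if o != DONOR:
                raise ValueError("marker is not on a donor segment")
            return marker_cM - s, e - marker_cM
    raise ValueError("marker outside haplotype")


def mosaic_flanking_lengths_cM(
    mosaic: GenomeMosaic, chrom: str, marker_bp: int, bp_per_cM: float
) -> tuple[float, float]:
    """Donor flank lengths (cM) around a marker in a bp mosaic."""
    for s, e, o in mosaic.intervals[chrom]:
        if s <= marker_bp - 1 < e:
            if o != DONOR:
                raise ValueError("marker is not on a donor segment")
            return (marker_bp - 1 - s) / bp_per_cM, (e - marker_bp + 1) / bp_per_cM
    raise ValueError("marker outside mosaic")


# ---------------------------------------------------------------------------
# RNA-Seq variant observation
# ---------------------------------------------------------------------------

def observe_variants(
    mosaic: GenomeMosaic | None,
    sites: pd.DataFrame,
    obs: ObservationModel,
    strain: str,
    seed: int | np.random.Generator,
    allele_column: str | None = None,
) -> tuple[StrainVariantTable, pd.DataFrame]:
    """Observe the divergent coding sites of one strain through RNA-Seq.

    ``strain`` is "donor", "recipient", or any label for a congenic animal
    (in which case ``mosaic`` decides the allele at every site).  Returns
    the VCF-style variant table (sites reported non-reference, with QUAL)
    and the covered reference-agreeing sites (chrom, pos) — the coverage
    evidence later needed to call recipient origin from variant absence.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if allele_column is None and strain in (DONOR, RECIPIENT):
        allele_column = f"{strain}_allele"
    if allele_column is not None:
        true_allele = sites[allele_column].to_numpy()
    else:
        if mosaic is None:
            raise ValueError("congenic observation requires a mosaic")
        sites = sites.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
        is_donor = np.zeros(len(sites), dtype=bool)
        for chrom in sites["chrom"].unique():
            mask = (sites["chrom"] == chrom).to_numpy()
            is_donor[mask] = mosaic.origins_at(chrom, sites.loc[mask, "pos"].to_numpy())
        true_allele = np.where(
            is_donor,
            sites["donor_allele"].to_numpy(),
            sites["recipient_allele"].to_numpy(),
        )

    n = len(sites)
    covered = rng.random(n) >= obs.coverage_dropout
    wrong = rng.random(n) < obs.error_rate
    ref = sites["ref"].to_numpy()
    alt = sites["alt"].to_numpy()
    # an error flips the reported state between ref and the site's alt allele
    reported = np.where(wrong, np.where(true_allele == ref, alt, ref), true_allele)
    is_variant = covered & (reported != ref)
    is_ref = covered & (reported == ref)
    qual = np.where(
        wrong,
        rng.uniform(obs.error_qual_min, obs.error_qual_max, size=n),
        rng.uniform(obs.true_qual_min, obs.true_qual_max, size=n),
    )
    variants = pd.DataFrame(
        {
            "chrom": sites["chrom"].to_numpy()[is_variant],
            "pos": sites["pos"].to_numpy()[is_variant],
            "ref": ref[is_variant],
            "alt": reported[is_variant],
            "qual": np.round(qual[is_variant], 2),
        }
    )
    covered_ref = pd.DataFrame(
        {
            "chrom": sites["chrom"].to_numpy()[is_ref],
            "pos": sites["pos"].to_numpy()[is_ref],
        }
    )
    return StrainVariantTable(strain=strain, variants=variants), covered_ref


# ---------------------------------------------------------------------------
# count simulation
# ---------------------------------------------------------------------------

def simulate_counts(spec: CountSimSpec) -> tuple[CountMatrix, pd.DataFrame]:
    """NB-distributed gene × sample counts with designated DE genes.

    Counts are Gamma–Poisson draws: ``K ~ Poisson(Gamma(1/α, μα))`` so that
    ``Var(K) = μ + α μ²``.  DE genes have their group-2 mean scaled by
    ``2**log2fc``.  Returns the matrix and the truth table
    (gene_id, is_de, log2fc).
    """
    rng = np.random.default_rng(spec.seed)
    n, m = spec.n_genes, spec.n_samples_per_group
    lo, hi = spec.nb_mean_range
    means = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n))
    n_de = int(round(spec.de_fraction * n))
    de_idx = rng.choice(n, size=n_de, replace=False)
    lfc = np.zeros(n)
    if n_de:
        lfc[de_idx] = rng.choice(np.asarray(spec.de_log2fc_values), size=n_de)
    mu1 = np.repeat(means[:, None], m, axis=1)
    mu2 = np.repeat((means * 2.0 ** lfc)[:, None], m, axis=1)
    mu = np.hstack([mu1, mu2])
    alpha = spec.nb_dispersion
    lam = rng.gamma(shape=1.0 / alpha, scale=mu * alpha)
    counts = rng.poisson(lam)
    gene_ids = [f"g{i:05d}" for i in range(n)]
    samples = [f"A{j+1}" for j in range(m)] + [f"B{j+1}" for j in range(m)]
    groups = pd.Series(
        ["group1"] * m + ["group2"] * m, index=samples, name="group"
    )
    matrix = CountMatrix(
        counts=pd.DataFrame(counts, index=gene_ids, columns=samples),
        groups=groups,
    )
    truth = pd.DataFrame(
        {"gene_id": gene_ids, "is_de": lfc != 0.0, "log2fc": lfc}
    )
    return matrix, truth


# ---------------------------------------------------------------------------
# published candidate-SNP fixture
# ---------------------------------------------------------------------------

_FIXTURE = "congenic_candidate_snps.tsv"


def load_candidate_snps() -> pd.DataFrame:
    """Load the packaged table of 22 published non-synonymous congenic-locus
    SNPs (gene, allele, CDS/protein position, AA and codon change, SIFT).

    Adds derived columns: ``ref_codon``/``alt_codon`` (upper case),
    ``changed_slot`` (1–3, the codon position that differs), ``coding_alt``
    (the alt base in coding orientation) and ``strand`` (inferred: '+' when
    the genomic alt allele equals the coding alt base, '-' otherwise).
    """
    with resources.files("introscan.data").joinpath(_FIXTURE).open() as fh:
        df = pd.read_csv(fh, sep="\t", dtype={"sift_score": str})
    df["sift_score"] = pd.to_numeric(df["sift_score"].replace("-", np.nan))
    ref_codon, alt_codon, slot, coding_alt, strand = [], [], [], [], []
    for row in df.itertuples(index=False):
        rc, ac = row.codon_change.split("/")
        slots = [i for i in range(3) if rc[i].isupper()]
        if len(slots) != 1 or [i for i in range(3) if ac[i].isupper()] != slots:
            raise ValueError(f"bad codon change {row.codon_change}")
        i = slots[0]
        ref_codon.append(rc.upper())
        alt_codon.append(ac.upper())
        slot.append(i + 1)
        coding_alt.append(ac[i].upper())
        strand.append("+" if ac[i].upper() == row.allele else "-")
    df["ref_codon"], df["alt_codon"] = ref_codon, alt_codon
    df["changed_slot"], df["coding_alt"], df["strand"] = slot, coding_alt, strand
    return df


def write_candidate_snp_fixture(path: str | Path) -> Path:
    """Write a verbatim copy of the packaged candidate-SNP table."""
    path = Path(path)
    data = resources.files("introscan.data").joinpath(_FIXTURE).read_text()
    path.write_text(data)
    return path


def gene_with_embedded_codon(
    symbol: str,
    cds_position: int,
    ref_codon: str,
    strand: str = "+",
    chrom: str = "chr1",
    gene_start: int = 1_000,
    min_codons: int | None = None,
    filler: str = "GCT",
) -> GeneModel:
    """Build a single-exon toy gene whose coding sequence carries
    ``ref_codon`` at the codon containing CDS position ``cds_position``.

    Used to exercise the consequence annotator against published
    annotations whose real transcript sequences are not shipped: everything
    outside the codon of interest is a neutral filler codon.
    """
    codon_idx = (cds_position - 1) // 3  # 0-based
    n_codons = max(codon_idx + 1, min_codons or 0) + 2
    seq = list(filler * n_codons)
    seq[3 * codon_idx : 3 * codon_idx + 3] = ref_codon.upper()
    seq = "".join(seq)
    cds_len = 3 * n_codons
    intervals = [(gene_start, gene_start + cds_len - 1)]
    return GeneModel(
        gene_id=symbol,
        symbol=symbol,
        chrom=chrom,
        strand=strand,
        cds_intervals=intervals,
        coding_sequence=seq,
    )


def variant_for_embedded_codon(
    gene: GeneModel, cds_position: int, coding_alt: str, qual: float = 200.0
) -> VariantCall:
    """The genomic-strand variant substituting ``coding_alt`` at
    ``cds_position`` of ``gene`` (alleles complemented on minus strand)."""
    gpos = gene.cds_to_genomic(cds_position)
    coding_ref = gene.coding_sequence[cds_position - 1]
    if gene.strand == "+":
        ref, alt = coding_ref, coding_alt
    else:
        ref = coding_ref.translate(_COMPLEMENT)
        alt = coding_alt.translate(_COMPLEMENT)
    return VariantCall(chrom=gene.chrom, pos=gpos, ref=ref, alt=alt, qual=qual)
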