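"""End-to-end run: simulate inputs, map introgressed segments, run DE,
annotate consequences, and nominate candidates — reproducible from a single
YAML config plus seed."""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import classify as _classify
from . import consequence as _consequence
from . import de as _de
from . import io as _io
from . import candidates as _candidates
from . import segments as _segments
from . import simulate as _simulate

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DetectionConfig:
    bin_width: int = _segments.FOCAL_BIN_WIDTH
    genome_bin_width: int = _segments.GENOME_BIN_WIDTH
    min_support: int = 3
    donor_fraction: float = 0.8
    max_gap_bins: int = 2

    def __post_init__(self) -> None:
        if self.bin_width <= 0 or self.genome_bin_width <= 0:
            raise ValueError("bin widths must be positive")


@dataclass(frozen=True)
class PipelineConfig:
    """Validated configuration for :func:`run_pipeline`.

    ``truth_segments`` (chrom -> [[start, end], ...] in bp, half-open)
    switches the congenic genome to fixed-truth mode; otherwise the mosaic
    is simulated by marker-selected backcrossing per ``breeding``.
    """

    seed: int = 0
    min_qual: float = 100.0
    focal_chrom: str = "chr1"
    strain: str = "congenic"
    genome: _simulate.GenomeSpec = field(default_factory=_simulate.GenomeSpec)
    breeding: _simulate.BreedingModel = field(default_factory=_simulate.BreedingModel)
    observation: _simulate.ObservationModel = field(
        default_factory=_simulate.ObservationModel
    )
    counts: _simulate.CountSimSpec = field(default_factory=_simulate.CountSimSpec)
    detection: DetectionConfig = field(default_factory=DetectionConfig)
    de: _de.DEConfig = field(default_factory=_de.DEConfig)
    truth_segments: dict | None = None

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        kwargs: dict = {}
        sections = {
            "genome": _simulate.GenomeSpec,
            "breeding": _simulate.BreedingModel,
            "observation": _simulate.ObservationModel,
            "counts": _simulate.CountSimSpec,
            "detection": DetectionConfig,
            "de": _de.DEConfig,
        }
        for name, klass in sections.items():
            if name in raw:
                sub = raw.pop(name)
                allowed = {f.name for f in dataclasses.fields(klass)}
                unknown = set(sub) - allowed
                if unknown:
                    raise ValueError(f"unknown keys in '{name}': {sorted(unknown)}")
                sub = {k: _tuplify(v) for k, v in sub.items()}
                kwargs[name] = klass(**sub)
        top_allowed = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - top_allowed
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs.update(raw)
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    def to_dict(self) -> dict:
        return _listify(dataclasses.asdict(self))


def _tuplify(value):
    """YAML lists -> tuples (recursively) so frozen dataclasses hash/compare."""
    if isinstance(value, list):
        return tuple(_tuplify(v) for v in value)
    return value


def _listify(value):
    """Tuples -> lists (recursively) so the config echo is plain YAML."""
    if isinstance(value, (list, tuple)):
        return [_listify(v) for v in value]
    if isinstance(value, dict):
        return {k: _listify(v) for k, v in value.items()}
    return value


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Run the full synthetic study; returns a dict of key results/paths.

    All randomness derives from ``config.seed``; the same config writes
    byte-identical result directories.
    """
    outdir = Path(outdir)
    inputs = outdir / "inputs"
    results = outdir / "results"
    inputs.mkdir(parents=True, exist_ok=True)
    results.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)

    logger.info("stage: simulate parental genomes")
    parents = _simulate.simulate_parental_genomes(
        dataclasses.replace(config.genome, seed=config.seed)
    )
    chrom_lengths = dict(config.genome.chromosomes)

    logger.info("stage: congenic mosaic")
    if config.truth_segments is not None:
        donor_segments = {
            c: [tuple(seg) for seg in segs]
            for c, segs in config.truth_segments.items()
        }
        mosaic = _simulate.GenomeMosaic.from_segments(chrom_lengths, donor_segments)
    else:
        breeding = dataclasses.replace(
            config.breeding, chrom_lengths_bp=tuple(chrom_lengths.items())
        )
        mosaic = _simulate.simulate_backcross(breeding, rng)

    logger.info("stage: observe variants")
    tables: dict[str, _io.StrainVariantTable] = {}
    covered: dict[str, pd.DataFrame] = {}
    for strain in (_simulate.DONOR, _simulate.RECIPIENT, config.strain):
        m = mosaic if strain == config.strain else None
        tables[strain], covered[strain] = _simulate.observe_variants(
            m, parents.sites, config.observation, strain, rng
        )
        _io.write_vcf(
            tables[strain], inputs / f"{_slug(strain)}.vcf",
            contigs=chrom_lengths, seed=config.seed,
        )
        _io.write_covered_sites(covered[strain], inputs / f"{_slug(strain)}.covered.tsv")
    _io.write_gff(parents.gene_models, inputs / "genes.gff3")
    _io.write_cds_fasta(parents.gene_models, inputs / "cds.fasta")
    parents.sites.to_csv(inputs / "truth_sites.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            (c, s, e, o)
            for c, ivs in mosaic.intervals.items()
            for s, e, o in ivs
        ],
        columns=["chrom", "start", "end", "origin"],
    ).to_csv(inputs / "truth_mosaic.tsv", sep="\t", index=False)

    logger.info("stage: read inputs back and quality-filter (QUAL >= %g)", config.min_qual)
    donor_t = _io.read_vcf(inputs / "donor.vcf", "donor", min_qual=config.min_qual)
    recipient_t = _io.read_vcf(inputs / "recipient.vcf", "recipient", min_qual=config.min_qual)
    congenic_t = _io.read_vcf(
        inputs / f"{_slug(config.strain)}.vcf", config.strain, min_qual=config.min_qual
    )

    logger.info("stage: classify SNP origin")
    partition = _classify.strain_specific_sites(donor_t, recipient_t)
    calls = _classify.classify_congenic_origin(
        congenic_t, partition, covered[config.strain]
    )
    calls.to_csv(results / "origin_calls.tsv", sep="\t", index=False)

    logger.info("stage: segment detection")
    det = config.detection
    focal_bins = _segments.bin_origin_calls(
        calls, bin_width=det.bin_width, chrom=config.focal_chrom,
        chrom_length=chrom_lengths[config.focal_chrom],
    )
    segs = _segments.detect_segments(
        focal_bins, min_support=det.min_support,
        donor_fraction=det.donor_fraction, max_gap_bins=det.max_gap_bins,
    )
    scan = _segments.genome_scan(
        calls, chrom_lengths, bin_width=det.genome_bin_width,
        min_support=det.min_support, donor_fraction=det.donor_fraction,
        max_gap_bins=det.max_gap_bins,
    )
    seg_df = pd.DataFrame(
        [
            (s.chrom, s.start, s.end, s.length_mbp, s.n_donor_snps, s.n_recipient_snps)
            for s in segs
        ],
        columns=["chrom", "start", "end", "length_mbp", "n_donor_snps", "n_recipient_snps"],
    )
    seg_df.to_csv(results / "segments.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            (c, s.start, s.end, s.length_mbp)
            for c, ss in scan.items()
            for s in ss
        ],
        columns=["chrom", "start", "end", "length_mbp"],
    ).to_csv(results / "genome_scan.tsv", sep="\t", index=False)

    logger.info("stage: differential expression")
    counts_spec = dataclasses.replace(config.counts, seed=config.seed + 1)
    matrix, de_truth = _simulate.simulate_counts(counts_spec)
    # anchor the simulated count rows to simulated gene models so that
    # DE genes have genomic coordinates for cross-referencing
    n_assign = min(matrix.n_genes, len(parents.gene_models))
    model_ids = [g.gene_id for g in parents.gene_models]
    assigned = list(rng.choice(model_ids, size=n_assign, replace=False))
    new_index = assigned + list(matrix.counts.index[n_assign:])
    matrix.counts.index = new_index
    de_truth = de_truth.assign(gene_id=new_index)
    _io.write_counts(matrix, inputs / "counts.tsv")
    de_truth.to_csv(inputs / "truth_de.tsv", sep="\t", index=False)
    matrix = _io.read_counts(inputs / "counts.tsv")
    de_results = _de.nb_test(matrix, config.de)
    de_results.to_csv(results / "de_results.tsv", sep="\t", index=False, float_format="%.6g")
    de_strict = _de.de_filter(de_results, "strict", config.de)

    logger.info("stage: candidate SNPs and consequences")
    loci = [(s.chrom, s.start, s.end) for s in segs]
    cand = _classify.candidate_snp_filter(donor_t, recipient_t, congenic_t, loci)
    gene_by_pos = _gene_lookup(parents.gene_models)
    records = []
    for row in cand.itertuples(index=False):
        gene = gene_by_pos(row.chrom, row.pos)
        if gene is None:
            continue
        try:
            rec = _consequence.annotate(
                _io.VariantCall(row.chrom, row.pos, row.ref, row.alt, 100.0),
                gene,
            )
        except ValueError:
            continue  # erroneous call inconsistent with the reference sequence
        records.append(rec)
    pd.DataFrame([dataclasses.asdict(r) for r in records]).to_csv(
        results / "consequences.tsv", sep="\t", index=False
    )

    logger.info("stage: nominate candidates")
    de_in_locus = _candidates.cross_reference(
        list(de_strict.gene_id), segs, parents.gene_models
    )
    candidates = _candidates.nominate(
        records, de_in_locus, config.strain, parents.gene_models
    )
    _candidates.write_report(
        candidates, results / "candidates.tsv", results / "candidates.txt"
    )

    with open(outdir / "config_echo.yaml", "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)

    return {
        "outdir": outdir,
        "mosaic": mosaic,
        "origin_calls": calls,
        "segments": segs,
        "genome_scan": scan,
        "cumulative_mbp": _segments.cumulative_length(segs),
        "de_results": de_results,
        "de_strict": de_strict,
        "consequences": records,
        "candidates": candidates,
    }


DEFAULT_TRUTH_SEGMENTS_BP = (
    (89_000_000, 97_000_000),
    (104_000_000, 105_100_000),
    (178_000_000, 210_000_000),
    (234_000_000, 274_000_000),
)


def simulate_and_detect(
    seed: int,
    truth_segments_bp=DEFAULT_TRUTH_SEGMENTS_BP,
    chrom_length: int = 290_000_000,
    snp_density: float = 15.0,
    observation: _simulate.ObservationModel | None = None,
    min_qual: float = 100.0,
    bin_width: int = _segments.FOCAL_BIN_WIDTH,
    **detect_kwargs,
) -> dict:
    """One in-memory replicate of the segment-recovery experiment.

    Simulates divergent parents on a single chromosome, imposes a
    fixed-truth donor mosaic, observes all three strains through the
    RNA-Seq noise model, applies the QUAL filter, classifies congenic
    ancestry, bins, and detects segments.  Returns truth and detected
    cumulative lengths plus the segment list.
    """
    observation = observation or _simulate.ObservationModel()
    rng = np.random.default_rng(seed)
    spec = _simulate.GenomeSpec(
        chromosomes=(("chr1", chrom_length),), snp_density=snp_density, seed=seed
    )
    parents = _simulate.simulate_parental_genomes(spec)
    mosaic = _simulate.GenomeMosaic.from_segments(
        {"chr1": chrom_length}, {"chr1": [tuple(s) for s in truth_segments_bp]}
    )
    tables, covered = {}, {}
    for strain in (_simulate.DONOR, _simulate.RECIPIENT, "congenic"):
        m = mosaic if strain == "congenic" else None
        table, cov = _simulate.observe_variants(
            m, parents.sites, observation, strain, rng
        )
        v = table.variants
        table.variants = v[v.qual >= min_qual].reset_index(drop=True)
        tables[strain], covered[strain] = table, cov
    partition = _classify.strain_specific_sites(
        tables[_simulate.DONOR], tables[_simulate.RECIPIENT]
    )
    calls = _classify.classify_congenic_origin(
        tables["congenic"], partition, covered["congenic"]
    )
    binned = _segments.bin_origin_calls(
        calls, bin_width=bin_width, chrom="chr1", chrom_length=chrom_length
    )
    segs = _segments.detect_segments(binned, **detect_kwargs)
    return {
        "segments": segs,
        "detected_mbp": _segments.cumulative_length(segs),
        "truth_mbp": sum(e - s for s, e in truth_segments_bp) / 1e6,
        "n_sites": len(parents.sites),
        "origin_calls": calls,
    }


def _slug(name: str) -> str:
    return "".join(ch if ch.isalnum() else "_" for ch in name).strip("_").lower()


def _gene_lookup(models):
    by_chrom: dict[str, list] = {}
    for g in models:
        by_chrom.setdefault(g.chrom, []).append(g)
    for lst in by_chrom.values():
        lst.sort(key=lambda g: g.span[0])

    def lookup(chrom: str, pos: int):
        for g in by_chrom.get(chrom, ()):
            start, end = g.span
            if start < pos <= end:
                try:
                    g.genomic_to_cds(pos)
                except ValueError:
                    continue
                return g
        return None

    return lookup
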