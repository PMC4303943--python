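# Methods

`introscan` maps the donor-derived chromosomal segments of an interval-specific
congenic strain from RNA-Seq coding SNPs, and nominates candidate genes by
combining two lines of evidence: non-synonymous SNPs inside the introgressed
loci and differential expression of genes overlapping those loci. This note
describes the models, the parameters that matter, the numerical choices, and
what the synthetic-data generator does and does not emulate.

## Study design being modelled

Two inbred strains: a disease-model *donor* and a healthy *recipient*. An
interval-specific congenic strain is produced by N generations of backcrossing
to the recipient while selecting offspring that retain the donor allele at one
or more markers. The congenic genome is therefore recipient everywhere except
for donor segments around the selected markers. Because only expressed coding
positions are visible to RNA-Seq, the genetic evidence is a set of coding SNP
calls per strain, quality-filtered at VCF QUAL ≥ 100 (configurable `min_qual`).

## Strain-of-origin classification

An alt allele seen in exactly one parent is strain-informative. At a
donor-specific site, the congenic strain carrying the donor alt is labelled
`donor_informative`; the congenic strain observed to match the reference is
labelled `recipient_informative`; symmetric logic applies at
recipient-specific sites. Sites where the two parental tables disagree on the
reference base are discarded.

**Absence handling.** RNA-Seq coverage is expression-dependent, so a record
missing from the congenic VCF is ambiguous: unexpressed, or truly reference.
Absence counts as reference evidence only when a coverage table marks the site
as observed; bare absence is `uninformative`. This avoids phantom recipient
segments across unexpressed regions, at the cost of discarding genuine
reference evidence when no coverage information is available.

Allele matching is exact on the alt base; indels and IUPAC ambiguity codes are
out of scope. Multi-allelic VCF records are split by default (the handling of
such sites is a package choice, not something the upstream study specifies).

## Segment delimitation

Informative calls are tallied into fixed-width bins (1 Mbp on the focal
chromosome, 10 Mbp genome-wide). A 1-based position p falls in bin
`p // width`, so a call exactly on a boundary belongs to the right-open bin
starting there. A bin is donor-labelled when

* donor-informative count ≥ `min_support` (default 3), and
* donor/(donor+recipient) ≥ `donor_fraction` (default 0.8).

Runs of donor bins are merged across gaps of at most `max_gap_bins` (default
2) bins that carry **no recipient-informative SNPs**: expression deserts are
tolerated rather than read as recipient origin, consistent with the absence
rule above. (Bins with some sub-threshold donor evidence and no recipient
evidence are also bridgeable; this keeps detection monotone in donor
evidence — adding donor SNPs inside a detected segment can never shrink it.)
Segment boundaries are the outer edges of the terminal donor bins, i.e.
reported at bin resolution, which is how the underlying evidence is plotted
and judged. An HMM-based segmentation would be the natural refinement and is
deliberately not implemented.

`cumulative_length` sums non-overlapping segment lengths in Mbp and rejects
overlaps.

## Backcross genetics

The expected residual donor DNA flanking a selected marker after N
backcrosses is 100/N cM per side (25 cM total at N = 8). The Monte-Carlo
simulator makes the assumptions behind that expectation explicit:

* **Haldane model** — crossovers per meiosis are Poisson with mean equal to
  the map length in Morgans; breakpoints are uniform on the genetic map; no
  interference.
* **Inbred parents** — both parents homozygous, so the congenic chromosome is
  tracked as a single haploid donor/recipient mosaic; the F1 contributes a
  whole-chromosome donor haplotype paired with a recipient homolog.
* **Marker-assisted selection** — each generation, gametes are drawn until
  one carries the donor allele at every selected marker (rejection sampling
  over meioses, mirroring selection among offspring). Chromosomes without
  markers segregate freely; their expected donor content halves each
  generation, (1/2)^N.
* **Uniform map** — genetic and physical coordinates interconvert at a single
  rate, `bp_per_cM` = 2×10⁶ by default; no recombination hot or cold spots.

The closed-form 100/N is exact only on an infinite chromosome; on a finite
arm the flank is truncated at the telomere, so Monte-Carlo means fall
slightly below 100/N when the marker sits within a few expected flank lengths
of a chromosome end.

## Synthetic data generator

The generator produces every input the pipeline consumes, with ground truth.

| parameter | default | rationale |
|---|---|---|
| chromosome | 290 Mbp | size of the focal rat chromosome |
| `coding_fraction` | 0.02 | mammalian-genome coding share |
| `snp_density` | 15 divergent coding sites / Mbp | qualitatively matches the binned SNP counts observed between divergent inbred strains; the study reports no exact totals, so this is calibrated to the plotted scale, not to a published number |
| `coverage_dropout` | 0.2 | RNA-Seq visibility limited to expressed transcripts |
| `error_rate` | 0.005 | wrong-allele calls surviving upstream filters |
| QUAL, true calls | uniform 100–255 | all pass the QUAL ≥ 100 filter |
| QUAL, erroneous calls | uniform 30–150 | the filter removes some but not all errors, so it is exercised meaningfully |
| `nb_dispersion` | 0.1 | typical RNA-Seq biological CV ≈ 0.3 |
| NB means | log-uniform 20–2000 | spans the expressed-gene filter ≥ 10 |

Gene models are single- or two-exon CDS of 300–2100 bp with random sense
codons; divergent sites are placed uniformly within CDS at the stated density
per Mbp of chromosome (positions drawn with replacement and deduplicated —
collisions are negligible at these densities). At each site one parent,
chosen with probability 1/2, carries a non-reference allele. An observation
error flips the reported state between the reference and the site's alt
allele; erroneous variant records draw their QUAL from the low range above.

**What the generator does not emulate:** read-level noise (FASTQ/alignment),
mapping bias, allele-specific expression, recombination hot spots, shared
ancestral polymorphism between the parents, mean-dependent NB dispersion,
and library-composition artefacts. Passing tests demonstrate correctness of
the pipeline's logic under these idealised conditions, not robustness to the
full messiness of real RNA-Seq.

## Differential expression

Median-of-ratios size factors (factor_j = median over genes with a positive
geometric mean of count_ij / geometric mean_i); a pseudo-reference over
positive counts is available behind a flag for matrices where no gene is
expressed in every sample. Genes with raw mean count below 10 are excluded
as low-count. log2FC is group2 vs group1 on normalized means with a 0.5
pseudocount, which bounds fold changes for zero-count groups.

Per-gene NB dispersion is estimated by method of moments on normalized
counts, pooling within-group variability across the two groups and
subtracting the normalization-weighted shot-noise term. Raw per-gene
estimates at n = 3 + 3 are extremely noisy and, used directly, make the test
anticonservative; they are therefore floored at the cohort median of the
tested genes (`dispersion_sharing="median_floor"`). This restores type-I
calibration under the generator's constant-dispersion counts and is
conservative for genes whose true dispersion is below the cohort's typical
value; with strongly mean-dependent dispersion a fitted mean–dispersion
trend would be the better floor. Groups with a single (pooled) sample are
tested only with a user-supplied fixed dispersion and emit a warning.

The test is a two-sided conditional exact test on the group count sums:
under the null the common normalized mean is estimated from the pooled
counts, each group sum is modelled as NB with matched moments
(mean q₀·Σs, variance q₀·Σs + α·q₀²·Σs²), and the p-value is the
probability, conditional on the total, of splits no more likely than the
observed one. Degenerate cases: total count 0 → p = 1; variance ≤ mean →
Poisson limit; numerical failure → gene excluded as non-converged.
Benjamini–Hochberg adjustment runs over tested genes only. Selection is
`padj < 0.1 & |log2FC| ≥ 1` (strict) or `pvalue < 0.05 & |log2FC| ≥ 1`
(relaxed).

Because the exact test conditions on raw group sums, rescaling one sample's
counts changes realized p-values even though size factors fully re-absorb
the scaling — the extra counts genuinely carry more shot-noise information.
Normalized means and log2FC are invariant; significance calls are stable but
not bit-identical. Gene lists will also differ from any particular external
DE tool's; the stage is validated by its simulation properties (type-I
error, FDR, power), not list identity.

## Consequence annotation

Genomic position → CDS offset is strand-aware (minus-strand genes use
reverse-complemented coordinates and alleles). The affected codon is
extracted, the alternate base substituted, and both codons translated with
the standard nuclear code — selenocysteine and non-standard codes are out of
scope. protein position = ⌈CDS/3⌉; the codon-change string upper-cases
exactly the substituted base (`Aga/Gga`). Stop gains are labelled `nonsense`
and excluded from missense candidate lists; stop losses fall under
`missense`. A mismatch between the VCF reference base and the coding
sequence raises an error naming both bases.

SIFT scores are inputs, never computed: ≤ 0.05 → `deleterious` (the boundary
is read as deleterious), otherwise `tolerated`, absent → `unscored`.

The packaged table of 22 published congenic-locus SNPs records, per variant,
the genomic-strand alt allele and the codon change in coding orientation;
comparing the two implies each gene's strand, which the loader derives
rather than stores. Tests rebuild each variant on a toy CDS embedding the
published codon at the published position and require the annotator to
reproduce every column.

## Candidate nomination

Polymorphic candidates: genes with ≥ 1 missense candidate SNP (donor and
congenic carry the alt; the recipient does not) inside a detected segment.
DE-in-locus candidates: DE genes whose gene body overlaps a segment — any
overlap by default, since segment boundaries have bin resolution and strict
containment would drop edge genes arbitrarily; full-containment mode is
available. The report lists both classes, their union, and their overlap
explicitly; gene order is deterministic (chromosome, then start).

## Problem sizes used in the shipped checks

The test suite and the acceptance script run entirely on synthetic data:
flanking-expectation Monte Carlo at 10,000 replicates on a 400-cM
chromosome with a central marker; segment recovery over 200 replicates of a
290-Mbp chromosome at 15 divergent sites/Mbp with the four truth segments
totalling 81.1 Mbp; DE calibration on 2,000-gene null matrices and 50
mixed-simulation replicates of 1,000 genes. These sizes give Monte-Carlo
standard errors comfortably inside the asserted tolerances.

## Known limitations

* Segment boundaries are bin-resolution; sub-bin refinement to the outermost
  informative SNP is not implemented.
* The absence rule trades sensitivity for specificity: without coverage
  tables, recipient-informative evidence is systematically under-counted.
* The DE stage assumes a two-group design; no covariates, no paired samples.
* The dispersion floor is a single cohort-wide constant (see above).
* The cM↔bp conversion is uniform; real genomes vary severalfold along a
  chromosome, so bp-scale flanking predictions are order-of-magnitude
  guides, not locus-specific estimates.
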