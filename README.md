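# introscan

Congenic-strain introgression mapping and candidate-gene nomination from
RNA-Seq coding SNPs.

## The problem

Interval-specific congenic strains — an inbred *recipient* genome carrying a
defined chromosomal segment from a disease-model *donor* strain, produced by
repeated marker-selected backcrossing — are a classical tool for confirming
quantitative trait loci (QTLs). Two questions follow every such cross:

1. **What was actually transferred?** After N backcrosses the donor segment
   retained around each selected marker is expected to span 100/N cM per
   side (≈12.5 cM per side at N = 8, with 1 cM ≈ 2×10⁶ bp), but the realised
   segment varies and must be mapped empirically. With RNA-Seq of the
   relevant tissue, coding SNPs that distinguish the parental strains act as
   ancestry-informative markers: the allele the congenic animal carries at
   each donor-specific or recipient-specific site reveals the local origin
   of its chromosome.
2. **Which genes in the transferred loci could drive the phenotype?**
   Candidates are genes with non-synonymous donor-specific SNPs inside the
   introgressed segments, and genes differentially expressed between the
   congenic and donor strains whose bodies lie within those segments.

`introscan` implements this workflow end to end: strain-specific SNP
classification from VCFs, binned segment detection, the 100/N backcross
arithmetic plus a Monte-Carlo backcross simulator (Haldane model,
marker-assisted selection), a self-contained negative-binomial
differential-expression stage (median-of-ratios normalization, pooled
method-of-moments dispersion with a cohort floor, two-sided conditional
exact test, Benjamini–Hochberg adjustment; selection at padj < 0.1 and
|log2FC| ≥ 1), strand-aware codon/amino-acid consequence annotation with
SIFT-score classification (≤ 0.05 deleterious), and the final candidate
report. A synthetic-data generator produces every input with known ground
truth — parental variant sets, congenic mosaics (simulated breeding or fixed
truth), RNA-Seq observation with coverage dropout and call errors, and NB
count matrices — so each stage is testable against truth. See
`docs/methods.md` for the models and their assumptions.

## Worked example

Generate a small synthetic study (a 60-Mbp focal chromosome with two planted
donor segments at 10–18 and 30–34 Mbp, plus a clean 30-Mbp background
chromosome) and run the full pipeline:

```bash
introscan simulate --preset small --seed 3 --outdir demo
introscan run -c demo/config.yaml --outdir demo/out
```

which prints

```
detected segments: 2 (cumulative 12.0 Mbp); strict DE genes: 35; candidates: 49
```

The detected segments (`demo/out/results/segments.tsv`) recover the planted
truth exactly at 1-Mbp bin resolution:

```
chrom   start     end       length_mbp  n_donor_snps  n_recipient_snps
chr1    10000000  18000000  8.0         125           0
chr1    30000000  34000000  4.0         36            0
```

and the candidate report (`demo/out/results/candidates.txt`) separates the
two evidence classes and their overlap:

```
polymorphic in locus : 45 gene(s)
DE within locus      : 4 gene(s)
overlap              : 0 gene(s)
union                : 49 gene(s)
```

45 genes carry a missense SNP present in donor and congenic but absent from
the recipient inside a detected segment; 4 of the 35 strict DE genes fall
inside a segment; no gene is nominated by both routes in this run. Per-SNP
consequence records (CDS position, protein position, codon and amino-acid
change, SIFT class) are in `demo/out/results/consequences.tsv`.

The same stages are available individually (`introscan classify`,
`segments`, `de`, `consequence`, `nominate`, `io validate`) and as library
functions; every flag mirrors a config key and every run is reproducible
from `config.yaml` + seed.

The package also ships a curated table of 22 published non-synonymous
congenic-locus SNPs (19 genes across the two loci of the rat chromosome-1
congenic strains WAG/OXYS-1.1 and WAG/OXYS-1.2); the consequence annotator
reproduces every row of it in the test suite, e.g. Hps5: CDS position 667 →
protein position 223, R/G, `Aga/Gga`.

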