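# Methods

## The calling model

The caller is heuristic/statistical in the VarScan lineage: hard filters
followed by a one-tailed Fisher exact test (FET).  All statistics at a
site are computed over one depth — the count of reads whose base quality
is at least `Qbase`; low-quality reads are excluded entirely, and
placeholder observations (`*` deleted bases, `>`/`<` reference skips)
count toward depth but can never be alleles.  VAF is therefore
variant-supporting reads over high-quality depth.

The error-null contingency table puts observed (variant, reference)
counts against expected counts at the same depth under a fixed per-base
substitution error rate.  The expected variant cell is
`floor(depth * err_rate)`: the floor makes every cell an integer and, at
any depth below 1/err_rate, makes a site with zero variant reads exactly
p = 1.  The one-tailed p-value sums hypergeometric probabilities of the
observed table and every table reached by moving the sweep cells toward
zero at fixed margins.  The sum is evaluated in log space (log-gamma plus
`logsumexp`), so deep sites underflow gracefully; genotype quality is
computed from the log p-value and capped at 255.

The paired-mode (somatic) table is oriented so that the swept tail runs
toward variant-allele *enrichment in the tumor*.  This is a directional
choice: depletion of a variant in the tumor relative to a heterozygous
normal is not significant under this tail and such sites fall through to
the Germline branch.  Only this orientation makes Somatic and LOH calls
(variant gained or made homozygous in the tumor) significant, which is
the classification the status rules require.

### Classification rules, exactly as implemented

- Both samples are genotyped independently with the full germline filter
  chain; a sample failing any filter is homozygous-reference (HOMREF).
- Genotypes match (same label, and same allele when non-HOMREF):
  Germline; VPV is recomputed on the pooled tumor+normal counts.
- Genotypes differ: a variant homozygous in the normal with a HOMREF or
  heterozygous tumor is Unknown outright.  Otherwise, if SPV <= 0.05:
  Somatic when the normal is HOMREF, LOH when the normal is
  heterozygous, Unknown otherwise.  If SPV > 0.05: Germline with pooled
  VPV.
- Confidence: Somatic is High iff tumor VAF >= 0.10, normal VAF < 0.05
  and SPV < 0.07; LOH is High iff normal VAF >= 0.10 and SPV < 0.07;
  Germline is High iff both VAFs >= 0.10; Unknown is always Low.

### Defaults and thresholds

| parameter | default | meaning |
|---|---|---|
| `qbase` | 15 | minimum Phred base quality per read |
| `rd_th` | 10 | minimum high-quality depth per site |
| `var_th` | 2 | minimum variant-supporting reads |
| `vaf_th` | 0.20 | minimum variant allele frequency |
| `vaf_homo` | 0.75 | VAF strictly above this is homozygous |
| `p_germline` | 0.01 | FET cutoff vs the error null |
| `p_somatic` | 0.05 | FET cutoff for somatic/LOH classification |
| `strand_frac` | 0.90 | discard if >= 90% / <= 10% of variant support on one strand |
| `err_rate` | 0.001 | error rate of the null model |
| `gq_cap` | 255 | maximum reported genotype quality |

Boundary conventions are deliberate and covered by tests: strand-bias
discards *at* the 90%/10% boundary (9 forward of 10 is discarded); the
homozygosity cutoff is strict (VAF exactly 0.75 is heterozygous); the
impact-score prioritization cutoff is strict (a score of exactly 0.65
does not count); a MAF of exactly 1% classifies as common; an exact
50/50 cohort allele split reports the alternate allele as the minor one.
Candidate alleles are ordered by count, then mean base quality, then
allele string — a full deterministic ordering.  The germline p cutoff is
0.01 by default but exposed, since 0.05 is also a defensible choice for
this statistic; both are available via `--p-value`.

Population-mode sites report at most two alternate alleles, ranked by
total supporting reads across samples; a sample whose allele is not
among the two, or which fails any filter, is coded 0/0 (not `./.`), and
MAF is computed from genotype allele copies (two per sample), not raw
read counts.

## Input handling

Only plain (optionally gzipped) mpileup text is read; BAM handling,
mapping-quality recalibration and duplicate marking are external
preprocessing (`samtools mpileup` with a mapping-quality filter and, for
BWA/Bowtie2 alignments, its mapping-quality adjustment).  Base qualities
are fixed at Phred+33.  Strand is taken from base-string case, which is
how the format encodes it and the only way the strand-bias filter can be
computed from mpileup.  Indels are anchored at the preceding base in
pileup space and left-anchored with the reference base in VCF space.

Annotation databases are replaced by five documented TSV schemas (impact
scores, known-variant rsIDs, clinical associations, per-gene
haploinsufficiency, drug associations) loaded and header-validated by
`AnnotationTables`; a deterministic fixture generator
(`write_example_tables`) produces schema-valid synthetic tables for
tests and demos.  Population allele-frequency tables (1000G/ExAC-style)
are not modeled.  The promoter window (2,000 bp upstream of the TSS,
strand-aware) and the splice-site window (2 intronic bases at each
junction) are conventional values, configurable on `GeneModel`.

## The simulation benchmark

The generator emulates the standard planted-variant design: a 16,569 bp
reference (generated uniformly at random from a seed; only its length
matters to the statistics), 12 SNVs per replicate planted one per
equal-width bin with at least read-length spacing and end margins, and
diploid construction by pairing the mutated sequence with itself
(homozygous) or with the reference (heterozygous).  Indel plans plant
one insertion and one deletion of each size in {1, 2, 5, 10} bp.  Reads
(default 100 bp) are drawn uniformly from both haplotypes to the target
mean coverage, with iid substitution errors (default 0.001) and constant
Phred-35 base quality, and are stacked into mpileup by their *true*
placement — no aligner runs.

What this does and does not show: passing benchmarks demonstrates the
caller's statistical behavior under its own error model — recall
reaching 1 at >= 40x, precision 1 even at 20x / 50 bp, exact recovery of
<= 10 bp indels at zero error.  It does not probe alignment artifacts
(mappability, GC bias, soft-clipping around indels), so the degradation
of large-indel recall at short read lengths seen with real aligners is
intentionally absent, and constant base qualities mean that raising
`Qbase` below 35 has no effect here (the non-increase of recall under a
stricter quality cutoff holds with equality).  Errors falling inside
simulated inserted bases are not modeled; reads ending inside an
insertion emit a truncated insertion token, which the VAF filter removes
from candidacy.

Benchmark metrics match calls to truth by exact
(chrom, pos, ref, alt) after left-anchoring; with an empty call set
precision is reported as 0.  Replicate averages use 20 seeded replicates
per condition (a compromise between sampling error and desk-scale
runtime; each replicate at 60x / 100 bp simulates ~10,000 reads).

## Known limitations

- Tumor purity, ploidy and subclonal heterogeneity are not modeled; VAF
  thresholds assume a diploid, pure sample.
- Multi-allelic sites report a single best allele in germline/somatic
  modes and at most two alleles in population mode.
- The somatic tail direction means tumor-depleted variants are never
  called LOH from the contrast alone (see above).
- Annotation quality is entirely bounded by the local tables supplied;
  impact scores exist only for variants present in the impact table
  (typically non-synonymous SNVs), and absent scores are treated as
  no-score rather than zero.
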