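# fetcall

Small-variant (SNV and short INDEL) detection, annotation and
prioritization from samtools-style mpileup input, built around a
one-tailed Fisher exact test against a sequencing-error-only null.  It is
aimed at desk-scale clinical/research sequencing analyses: single-sample
germline calling, paired tumor-normal somatic classification, cohort
genotyping with minor-allele frequencies, rule-based annotation from
local lookup tables, and a read-simulation benchmark for validating the
caller end to end.

## The statistical model

At each pileup position, reads with base quality below `Qbase` (default
Phred 15) are dropped.  A site is considered when the high-quality depth
is at least `RD_th` (default 10); an allele is a candidate when it is
supported by at least `VAR_th` reads (default 2) at a variant allele
frequency `VAF >= VAF_th` (default 0.20) and its support is not
concentrated (>= 90%) on one strand.

The candidate is tested against the null that all non-reference reads are
sequencing error.  With N(obs) high-quality reads, the expected split
under a per-base error rate e = 0.001 is
N(exp,var) = floor(N(obs) x e) variant and N(exp,ref) = N(obs) - N(exp,var)
reference reads.  Observed and expected counts form a 2x2 contingency
table with fixed margins, and the one-tailed p-value (the *variant
p-value*, VPV) sums the hypergeometric probabilities

    P = C(N(var), N(obs,var)) C(N(ref), N(obs,ref)) / C(N, N(obs))

of the observed table and every more-extreme table obtained by reducing
the smallest cell to zero.  A call is made when VPV <= 0.01, with
genotype quality GQ = -10 log10(VPV) and genotype HOM when
VAF > `VAF_homo` (default 0.75), else HET.

In paired mode both samples are genotyped independently; when the
genotypes disagree, the same one-tailed test on the tumor-vs-normal
allele counts (the *somatic p-value*, SPV, tail oriented toward variant
enrichment in the tumor) classifies the site as **Somatic** (normal
homozygous-reference), **LOH** (normal heterozygous), or **Unknown**,
with **Germline** otherwise (VPV recomputed on the pooled counts).
Somatic calls are **High** confidence when tumor VAF >= 10%, normal
VAF < 5% and SPV < 0.07.  Population mode applies the germline logic per
sample, codes genotypes 0/0, 0/1, 1/1 (0/2 for a second allele), and
reports the minor allele frequency (MAF) from genotype allele copies.

Annotation is a pure local join: gene-locus category (synonymous /
missense / nonsense / frameshift / inframe indel / splice site / UTR /
intron / promoter / intergenic) from a gene model plus reference
sequence, then three evidence categories from TSV tables — functional
impact scores (SIFT, PolyPhen2, MutationTaster, PhyloP, LRT), clinical
associations, and drug associations.  Priority is **High** when a score
exceeds 0.65 *and* a clinical *and* a drug association exist, **Medium**
with at least one category, **Low** otherwise.

## Worked example

Simulate a 4,000 bp genome with 4 planted homozygous SNVs, 80 bp reads at
40x with error rate 0.001, call variants, and score against the truth:

```sh
fetcall simulate --ref-length 4000 --n-snv 4 --coverage 40 --read-len 80 \
    --seed 7 --out-mpileup sim.mpileup --out-truth truth.vcf
fetcall germline sim.mpileup -o calls.vcf
fetcall evaluate truth.vcf calls.vcf
```

which prints

```
simulated 2000 reads over 4000 bp
4 variants written to calls.vcf
{
  "tp": 4, "fp": 0, "fn": 0,
  "sensitivity": 1.0, "precision": 1.0, "f_score": 1.0
}
```

and `calls.vcf` contains, for example,

```
#CHROM  POS   ID  REF  ALT  QUAL   FILTER  INFO         FORMAT           SAMPLE
ref     879   .   T    C    218.4  PASS    VPV=1.451e-22  GT:GQ:DP:AD:FREQ  1/1:218.4:38:38:100.00%
```

a homozygous call (GT 1/1) at depth 38 with all reads supporting the
alternate allele and GQ = -10 log10(VPV) capped at 255.  All four planted
SNVs are recovered with no false positives (sensitivity = precision = 1).

Other subcommands: `somatic` (two-sample mpileup in, STATUS/CONF-tagged
VCF out), `split` (one VCF per status), `population`, `annotate`,
`recurrent`, and the Fisher thresholds are exposed as `--Qbase`,
`--RD_th`, `--VAR_th`, `--VAF_th`, `--VAF_homo`, `--Strand_Bias`,
`--p-value`, `--somatic-p-value`.

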