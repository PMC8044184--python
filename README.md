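# cohortsnv

Joint Bayesian re-calling of somatic single-nucleotide variants (SNVs)
across multiple tumor samples from the same patient.

## The problem

Single-sample somatic callers (Mutect2, Strelka2, and friends) evaluate each
tumor/normal pair in isolation. At low variant allele frequency (VAF) a
handful of variant reads in one sample is hard to distinguish from
sequencing error, so real subclonal mutations are discarded. But when
several samples of the same tumor are available — multi-region biopsies,
primary/relapse pairs, longitudinal liquid biopsies — the chance that the
*same* error recurs at the *same* locus in several samples is tiny, while a
real subclonal SNV tends to show up in every sample that contains the
clone. `cohortsnv` exploits this: it takes the permissive per-sample call
sets of any single-sample caller, forms the union of candidate loci, and
re-scores every locus jointly across all samples.

## The model

At a candidate locus with homozygous normal allele $\mathcal{N}$ and a
single candidate tumor allele $\mathcal{T} \ne \mathcal{N}$, each tumor
sample $i$ of $m$ carries a binary indicator $z_i$ (sample has the SNV) and
a latent VAF $f_i$ with

$$f_i \mid z_i = 1 \sim \mathrm{Uniform}[\epsilon, 1], \qquad
  f_i \mid z_i = 0 = 0, \qquad \epsilon = 0.05 .$$

Each error-free base is $\mathcal{T}$ with probability $f_i$; the observed
base $b_{ij}$ equals the error-free base with probability $1 - q_{ij}$ and
each of the three other bases with probability $q_{ij}/3$, where $q_{ij}$
is the read's Phred-derived error probability. The prior over the indicator
vector $\mathbf{z}$ puts mass $1-\mu$ on $\mathbf{z} = \mathbf{0}$ and
spreads $\mu$ uniformly over the $2^m - 1$ remaining vectors (default
$\mu = 10^{-3}$). The reported **somatic probability** is

$$P(\mathbf{Z} \ne \mathbf{0} \mid \mathcal{N}, \mathbf{b}, \mathbf{q})
  = 1 - \frac{\sum_{\mathcal{T} \ne \mathcal{N}} (1-\mu) \prod_i
      P(\mathbf{b}_i \mid z_i = 0, \mathcal{T}, \mathcal{N})}
    {\sum_{\mathcal{T} \ne \mathcal{N}} \sum_{\mathbf{z}}
      P(\mathbf{b} \mid \mathbf{z}, \mathcal{T}, \mathcal{N})
      P(\mathbf{z})} ,$$

with the inner $2^m$-term sum collapsed to a linear-time product form. The
tumor allele $\mathcal{T}^*$ is the maximizer of the per-allele marginal
(already computed in the denominator). A Phred-scaled **TIN score**
($-10 \log_{10}$ of the posterior that the *normal* sample carries
$\mathcal{T}^*$) flags tumor-in-normal contamination; empirical filters
flag thin normal coverage, weak tumor support, one-strand-only support and
clustered call sites. By default these filters remove only calls that no
single-sample caller had accepted. When exactly one tumor sample has
variant reads, the decision defers to the original caller.

## Worked example

Simulate a small five-sample cohort and re-call it jointly:

```bash
cohortsnv simulate --outdir demo --seed 7 --n-true 30 --n-null 30
cohortsnv call \
  --normal demo/alignments/normal.sam \
  --tumor demo/alignments/tumor1.sam ... --tumor demo/alignments/tumor5.sam \
  --candidates demo/candidates/tumor1.candidates.vcf ... \
  --candidates demo/candidates/tumor5.candidates.vcf \
  --reference demo/reference.fa --output demo/calls.vcf
```

prints

```
candidates evaluated: 47
  skipped non-SNV records: 0
  all-normal (no call): 1
  deferred to single-sample caller: 11
  below posterior threshold: 6
  removed by filters: 1
    flag low-tumor-support: 1
    flag TIN: 2
calls written: 28
```

47 distinct loci were nominated by the permissive pseudo-caller; one had no
non-reference read in any sample, eleven had variant reads in a single
sample only and no original acceptance (deferred), six scored below the
0.5 posterior threshold, and one flagged novel call was removed. The output
VCF starts

```
#CHROM POS  ID REF ALT QUAL FILTER INFO                       FORMAT       tumor1 ...
sim1   100  .  G   A   .    PASS   PROB=1;TIN=28.47;NSUP=5    DP:TCOUNT:SB:ZS 55:17:10,7:1 ...
sim1   1100 .  T   C   .    PASS   PROB=1;TIN=32.62;NSUP=5    DP:TCOUNT:SB:ZS 66:5:2,3:1 ...
```

`PROB` is the somatic probability, `TIN` the contamination score (≥ 20 is
clean), `NSUP` the number of supporting samples; per sample, `DP` is the
quality-filtered depth, `TCOUNT` the tumor-allele read count, `SB` its
forward,reverse strand split and `ZS` the 0/1 support call. The record at
position 1100 shows the method's point: tumor1 holds only 5 variant reads
in 66 — weak evidence alone, decisive jointly.

Sweep the posterior threshold into a precision-recall curve with

```bash
cohortsnv bench pr-curve --calls demo/calls.vcf --truth demo/truth.tsv
```

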