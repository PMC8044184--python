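# Methods

## Model

Loci are evaluated independently. The normal sample is assumed homozygous
for a single allele N (taken from the REF column of the nominating VCFs and
optionally cross-checked against the reference FASTA); heterozygous normals
and multi-allelic tumor sites are out of scope. Exactly one alternative
allele T ≠ N is modeled per locus; T is not taken from the input VCFs but
re-estimated by maximum likelihood over the three alternatives.

For tumor sample i with n_i quality-filtered reads, the per-read emission is
`1 − q` for a base matching the latent error-free base and `q/3` otherwise
(errors unbiased over the three other nucleotides), where q is the read
base's Phred-derived error probability. The error-free base is T with
probability f_i. Conditional on the binary somatic indicator z_i, the VAF
f_i is either exactly 0 (z_i = 0, a Dirac point mass) or uniform on
[ε, 1] (z_i = 1). The full-pileup likelihood carries the multinomial
coefficient over the (N, T, other) partition of the bases; because that
partition depends on T, the coefficient does not cancel in the sum over
candidate tumor alleles and is computed per (sample, T), multiplying the
z = 0 and z = 1 likelihoods identically.

The prior over indicator vectors is `1 − μ` for the all-zero vector and
`μ / (2^m − 1)` for each of the others. The 2^m-term marginal collapses
exactly to

    (1 − 2^m/(2^m − 1)·μ) · Π_i P0_i  +  μ/(2^m − 1) · Π_i (P0_i + P1_i),

evaluated with a signed log-sum-exp (the first coefficient goes negative
for μ > (2^m − 1)/2^m, which the sign-aware reduction handles; the total is
a probability and stays positive). Correctness of this collapse is tested
against explicit enumeration up to m = 12 at relative error 1e−10.

Samples whose pileup is empty or contains only N are omitted before the
joint computation: they carry no evidence for any T, and in large numbers
they would drive the posterior toward zero. If every sample is omitted the
locus yields no record (logged), since candidates without any
non-reference read carry nothing to re-call.

### Tumor-in-normal (TIN) score

The TIN score is −10·log10 of the posterior that the *normal* sample
carries T, computed by extending the indicator prior verbatim to the
(m+1)-vector (Z_0, z): all-zero gets 1 − μ, each other vector
μ/(2^(m+1) − 1). Every vector with Z_0 = 1 is nonzero, so the numerator
retains the linear-time product form. The log base is 10 (Phred
convention), consistent with the default threshold 20 ≈ posterior 0.01.
The prior extension is isolated in one function so an alternative joint
prior can be swapped in.

### Per-sample support

The per-sample support bit reported in the output (ZS) is: the sample has
at least one quality-filtered T read *and* its individual posterior
P(z_i = 1 | b_i) under an indifferent prior (μ′ = 0.5), i.e. P1 > P0. This
rule is a documented design choice of this package; it is deliberately
prior-free so that support reflects the sample's own evidence rather than
the cohort-level μ.

## Parameters

| parameter | default | meaning |
|---|---|---|
| μ (`mu`) | 1e−3 | prior somatic probability per candidate locus. Candidates arrive pre-enriched by a permissive caller; the bundled simulator also plants true SNVs at the per-base rate 0.001, making the default self-consistent. Exposed on the CLI. |
| ε (`epsilon`) | 0.05 | lower truncation of the VAF prior given z = 1; keeps the "variant present" hypothesis away from the error-dominated f → 0 corner. |
| `call_threshold` | 0.5 | posterior cutoff for emitting a call; swept for PR curves. |
| `tin_threshold` | 20 | Phred TIN cutoff (strictly below flags). |
| `mapq_min` / `baseq_min` | 30 / 13 | read/base quality filters, strictly-below semantics. |
| `quad_order` | 32 | minimum Gauss–Legendre order (see below). |

## Numerical choices

* All likelihoods live in log space; scipy's `logsumexp`/`gammaln` and a
  per-read linear-in-f factorization keep everything finite for depths of
  10,000 reads at q = 1e−5 (tested).
* The z = 1 integrand is a polynomial in f of degree n_i, so Gauss–Legendre
  quadrature on [ε, 1] with order `max(32, ⌈(n_i+1)/2⌉)` integrates it
  exactly up to round-off; it is validated against an independent dense-grid
  (1e5-point composite Simpson) oracle at relative error 1e−8.
* Phred qualities convert as q = 10^(−Q/10), clamped to [1e−10, 0.75]:
  q = 0 is degenerate and q ≥ 0.75 makes the emission uninformative.
* Tumor-allele ties break lexicographically (A < C < G < T) for
  cross-platform determinism; calling is entirely deterministic for fixed
  inputs (byte-identical output VCFs, tested).
* The cluster filter reads "≥ 3 SNV sites within 100 bp" as inclusive span:
  max(pos) − min(pos) ≤ 100 over some window of ≥ 3 called sites, all
  members flagged. The empty-strand filter fires when one entire strand
  lacks T reads across *all* samples.

## Pileup layer

Reads flagged duplicate/secondary/supplementary are excluded by default
(switchable); deletions, reference skips and clips at the locus contribute
nothing. Overlapping mates count independently by default, with a switch to
keep only the higher-quality mate — which of the two conventions real
pipelines use varies, so both are available. Plain SAM input is loaded into
memory and realignment-merged once at the read-set level (adequate for
candidate-driven workloads; this layer targets thousands of loci, not
whole-genome streaming). Indexed BAM/CRAM input is fetched per locus, and
the realignment merge then happens on the per-locus fetched sets; a
realigned read that moved *away* from a locus consequently no longer masks
its original copy there — a rare edge that whole-file merging (SAM path)
handles exactly.

## Synthetic cohorts

The generator emulates bulk sequencing of a tumor with a linear clonal
phylogeny: clone k inherits all mutations of clones 1..k−1, so a mutation
introduced at clone k has VAF `0.5 · Σ_{j ≥ k} prevalence[s, j]` in sample
s (heterozygous, copy-neutral). The default mixture of five samples over
four clones is chosen so that every clone is detectable in at least two
samples and the terminal clone's mutations stay at VAF ≤ 0.1 everywhere —
the stratum single-sample callers miss. Depth is Poisson (default mean
60×), Phred qualities come from a three-point distribution centered on the
requested mean error rate (default 1%), strands are Bernoulli(½), and reads
are emitted as minimal single-base SAM records with correct flags, MAPQ and
qualities. A deliberately simple permissive pseudo-caller (nominate at ≥ 2
non-reference reads; accept at ≥ 4 ALT reads and ≥ 10% ALT fraction, plus
an explicit per-sample false-nomination rate on non-variant loci) produces
the candidate VCFs, so the defer rule and novel-only filtering are
exercised end to end.

What the simulator does *not* model: alignment artifacts, indels, copy
number, mate-pair geometry, GC and strand biases, contamination of the
normal, and germline heterozygosity. Passing the end-to-end benchmark
therefore demonstrates correctness of the probabilistic machinery and
plumbing under the stated generative model, not performance on real tumors.

## Calibration note

With μ = 1e−3, two samples at depth 60 and a true VAF right at 0.1, a few
percent of loci draw ≤ 8 variant reads in total — evidence for which a
calibrated posterior genuinely stays below 0.99 (verified against the
brute-force enumeration oracle). The Monte-Carlo calibration test therefore
samples VAF across the informative range [0.1, 0.5] rather than pinning
every locus to the boundary; posterior separation (> 0.99 for true loci,
< 0.01 for error-only loci) then holds with failure rate well under 1%.

## Benchmark sizes

The default benchmark cohort (acceptance script and end-to-end tests) uses
5 tumor samples, 500 true SNVs plus 500 non-variant loci at mean depth 60×
— large enough for stable precision/recall estimates at the default
threshold while keeping a full run in tens of seconds. Oracle-equivalence
checks use 1000 randomized cases up to m = 12 (marginal collapse) and
25 randomized pileups up to depth 200 (quadrature).

## Known limitations

* One tumor allele per locus; homozygous normals only.
* SNVs only — no indels or structural variants.
* μ is a single global prior; no site-specific mutation-rate model.
* The per-sample support rule and the TIN joint prior are package design
  choices where the underlying method leaves the detail open; both are
  isolated and documented above.
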