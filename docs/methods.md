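# Methods

This note documents the models implemented in `steppeadmix`, the
defaults and why they were chosen, what the synthetic-data generator does
and does not emulate, and the numerical choices that matter. Nothing
here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Genotype model

Low-coverage ancient individuals are represented pseudo-haploidly: at
each site covered by at least one sequencing read, one read is drawn
uniformly at random and its allele doubled, giving calls in {0, 2} with
9 for missing (EIGENSTRAT convention). This discards heterozygosity but
makes a single unbiased allele draw per individual per site, which is
what every downstream frequency-based statistic needs. Bases must
already have passed the base/mapping quality thresholds (the Q30/q30
convention) before counting. Pileup bases matching neither panel allele
are dropped before the draw: the panel is biallelic and the third allele
is overwhelmingly damage or error; this is a declared choice, as the
handling of triallelic pileups is ambiguous in the field.

Deamination damage is handled by end-masking: the outermost 2 bases of
UDG-half reads and 10 of non-UDG single-stranded reads are excluded for
C/T and G/A SNPs; transversion SNPs use unmasked reads. Masking is
idempotent and strand-agnostic (symmetric clipping). Damage profiling
(5' C>T, 3' G>A rate per position, window K = 15) always runs on
unmasked reads, since masking would erase the signal it measures.

## Synthetic data

The generator produces drifted allele frequencies, admixed individuals
with recorded ancestry tracts, reads with terminal damage, pedigrees,
and sex-dependent coverage. Conditions are fixed once as a realistic
desk-scale cohort and used everywhere:

* **Panel**: 50,000 autosomal SNPs, 22 chromosomes of 1 Morgan, evenly
  spaced; X is 1.8 model-autosome lengths at the same per-Morgan density
  (the real X:autosome genetic-length ratio), ~4,100 SNPs. Transitions
  are oversampled (~66%) as on capture panels.
* **Frequencies**: ancestral p ~ Uniform(0.05, 0.95) per SNP;
  populations drift along a small tree by Balding–Nichols steps,
  p' ~ Beta(p(1−F)/F, (1−p)(1−F)/F). Fixed alleles stay fixed. The
  default ten-population graph has a deep outgroup, a western clade
  (WSH source + four outgroups) and a nested eastern clade (onge basal;
  ami/han on one branch; mixe sharing a node with the ANA source). The
  nesting matters: qpAdm's outgroups must be differentially related to
  the sources, and to candidate wrong sources such as han, for the rank
  test to have power.
* **Admixture**: single pulse G generations ago; along each haploid
  chromosome, switch points arrive as a Poisson process of rate G per
  Morgan and each new tract draws its ancestry from the mixture
  proportions. This yields ancestry covariance proportional to
  exp(−G·d) exactly, and mean inter-switch tract length 1/G. Continuous
  or multi-pulse gene flow is out of scope (the dating model assumes a
  pulse).
* **Reference samples**: 12 pseudo-haploid individuals per population
  with 10% missingness; targets: 16 individuals. Default target: 30%
  WSH / 70% ANA, G = 10.
* **Reads**: depth ~ Poisson(mean); allele from the genotype with
  symmetric error ε; damage applies C→T (5') and G→A (3') flips with
  probability decaying exponentially from the read end (position-1 rate
  = the nominal damage rate, decay scale 3 positions, read length 60).
  Per-read records are capped (default 2,000/individual) to bound
  memory; counts are always exact.
* **Sex coverage**: expected per-site coverage is
  depth × copies/2 × efficiency, with X/Y capture efficiency 0.8 so
  females sit near X-ratio 0.8 and males near 0.4/0.4.

What the generator does **not** emulate: linkage disequilibrium within
source populations (SNPs are exchangeable given the graph), reference
bias, contamination reads, sequencing-quality variation, selection, and
real SNP ascertainment. Passing tests therefore demonstrate correctness
of the estimators under the stated generative model, not robustness to
every artefact of real capture data.

## f-statistics and the jackknife

Frequencies are sample means of allele draws (1 per pseudo-haploid, 2
per diploid individual). Statistics are complete-case per computation;
sites are dropped when any involved population lacks data. Blocks are
contiguous 5 cM windows by genetic position (last block of a chromosome
may be short). The weighted delete-one-block jackknife uses per-block
SNP counts as weights and reduces to the textbook jackknife for equal
weights. No inbreeding or small-sample correction is applied to the f3
apex: comparisons are relative and the apex is a fixed panel.

## qpWave / qpAdm

With left populations L = {target, k sources} and right populations R
(m outgroups; eight by default), X[i][j] = f4(L0, Li; R0, Rj) is fitted
at rank r by alternating least squares (SVD start, convergence when the
objective changes < 1e-8, ≤ 1,000 iterations) under the block-jackknife
covariance Q of vec(X); the minimized value is chi-square with
dof = (|L|−1−r)(|R|−1−r). qpAdm uses r = k−1 (so dof = m−k) and reads
the weights off the left null vector of the fitted matrix, normalized to
sum to 1. Out-of-[0,1] weights are reported and flagged infeasible,
never clipped.

Two numerical choices deserve note:

* **Weight covariance shrinkage.** The GLS weighting inverts a
  (|L|−1)(|R|−1)-dimensional Q estimated from the blocks. With 440
  autosomal blocks this is unproblematic, but a single-chromosome fit
  (X: 36 blocks for a 14-dimensional Q) makes the raw inverse unstable.
  The weighting therefore applies Schäfer–Strimmer shrinkage of Q's
  off-diagonal (analytic intensity from the per-block contributions);
  the intensity is ≈ 0 with many blocks, so autosomal results are
  unaffected. The model chi-square keeps the unshrunk Q.
* **Weight SEs re-estimate everything.** Each delete-one-block refit
  recomputes the covariance from the remaining blocks before refitting,
  so noise in Q itself propagates into the jackknife SEs; with the
  covariance held fixed, X-chromosome SEs understate the weight spread
  substantially.

Near-singular covariances (condition number > 1e10) are
ridge-regularized by 1e-4 × mean diagonal.

**Sex bias.** Z = (P_A − P_X)/√(σ_A² + σ_X²) from autosomal and X-only
fits of the same model; positive Z means the ancestry is enriched on
autosomes, i.e. male-driven admixture. *Limitation*: for very recent
admixture the 5 cM jackknife blocks are shorter than the ancestry
tracts (mean 1/G Morgans), adjacent blocks are correlated, and all
jackknife SEs — hence Z — become anticonservative by roughly 15% in SD
at G = 10. The null-calibration experiments therefore use G = 40
(tracts ≈ 2.5 cM), where the block-independence assumption holds; for
applications to admixture younger than ~20 generations, Z values near 2
should be read cautiously. The same caveat applies to any block
jackknife at fixed block size, including the original tools.

## Admixture dating

Per SNP, u = a − b and r = g/2 − (αa + (1−α)b) with α estimated by
pooled least squares of (g/2 − b) on u (the upstream tool leaves this
estimator unstated; plain least squares is used and reported). Products
(u_i r_i)(u_j r_j) are summed over individuals, binned by |Δ genetic
distance| (bin 0.001 Morgan, pairs to 1 Morgan, within chromosomes
only), and normalized by observed pair counts. On evenly spaced maps
the per-offset pair sums are computed for all offsets at once by FFT
autocorrelation; a general O(n²) path handles uneven maps, and the two
agree to floating precision.

The fit A·exp(−n·d) + c runs from 0.45 cM upward, weighted by bin pair
counts (bin variance scales inversely with pairs; unweighted fitting
lets the sparse short-distance bins bias n upward), with n bounded to
[0, 500] since rates above ~1/fit-start are unresolvable. SEs come from
a leave-one-chromosome jackknife with per-chromosome SNP counts as
weights; a non-positive fitted amplitude is reported as "no detectable
admixture decay" rather than a date. Calendar conversion uses 29
years/generation and adds the sample age, combining variances in
quadrature under independence. Uniform SNP weighting is used (the
upstream tool's low-frequency weighting is undocumented).

## Kinship

m = mismatch rate over sites called in both individuals (autosomes
only). Baseline m0 per group: median of within-group pair rates after
one round of excluding pairs below 0.75× the median (relatives only pull
the rate down); groups with < 3 pairs fall back to the global median.
r̂ = 2(1 − m/m0); degree cutoffs at midpoints of the expected m/m0
values (0.625 / 0.8125 / 0.90625). Classification requires ≥ 3,000
overlapping sites, where the binomial SE of m (~0.008) is small against
the class gaps. Pairs with m > 1.2·m0 warn (contamination or ancestry
mismatch) and classify unrelated. Degrees beyond second are not
resolved.

## Sex typing and screening

F requires X-ratio ≥ 0.6 and Y-ratio ≤ 0.1; M requires X-ratio ≤ 0.6
and Y-ratio ≥ 0.2; otherwise undetermined. The observed modes (~0.8
female, ~0.4 male on capture data) motivate the boundaries, which are
declared defaults rather than derived quantities. Screening fails on
endogenous DNA < 0.1%, < 10,000 SNPs covered, any contamination
estimate > 5%, or undetermined sex; boundary values pass. Contamination
estimates are consumed as external numbers — the mitochondrial and
male-X estimation algorithms are established third-party methods, not
reimplemented here.

## Allele frequencies from read counts

L(f) = Π_ind Σ_{g∈{0,1,2}} Binom(g; 2, f)·Binom(d; n, p_g) with
p_g = (g/2)(1−ε) + (1−g/2)ε and Hardy–Weinberg genotype priors within
the group; ε defaults to 0.001. The MLE is located on a 0.001 grid and
refined by bounded scalar minimization; the SE uses the numeric second
derivative of log L. At boundary MLEs (f̂ = 0 or 1) the SE is replaced
by the one-sided distance at which log L drops by 0.5, keeping error
bars defined. For C/T and G/A loci, counts must come from end-masked
reads (the genotype pipeline's convention).

## PCA projection

Components come from reference individuals only (missing reference
calls mean-imputed, per-SNP scaling by √(p(1−p)), SVD); monomorphic
SNPs are dropped. Ancient individuals are never imputed: each is
projected by ordinary least squares of its observed normalized calls on
the loadings, requiring ≥ 5,000 observed SNPs by default. Axis signs
are anchored so a designated reference population has positive mean
score, making outputs deterministic.

## Problem sizes used in validation

The validation suite and `scripts/acceptance.py` run at the study
conditions above (50k SNPs, 12 reference individuals/population, 10%
missingness, 16-individual targets). Replicate counts: qpAdm weight
recovery 8 seeds per mixture proportion across five proportions;
qpWave null calibration 200 seeds; dating 20 seeds per pulse age at
G ∈ {5, 10, 20}; sex-bias null 150 seeds at G = 40 (a 40-seed binomial
check of a 95% property carries ±3.4% noise, so the larger sample is
needed for a stable verdict); allele-frequency coverage 200 replicates
at 20 individuals × 2× depth. The reproduction script uses somewhat
fewer replicates per experiment, as it reports point estimates rather
than pass/fail verdicts.
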