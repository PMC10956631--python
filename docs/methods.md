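# Methods

This note documents the statistical procedures, the synthetic generative
model, and the numerical and design choices behind `eqthm`. Nothing here
states an empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## 5hmC estimation and classification

Paired arrays measure each CpG twice: the BS beta reads 5mC + 5hmC, the
oxBS beta 5mC only. The estimator is the clamped difference
`hmc = max(betaBS − betaOxBS, 0)` — a deliberate simplification of
signal-level maximum-likelihood estimators, chosen because every downstream
statistic consumes 5hmC proportions, and signal-level (IDAT) data is out of
scope. The function is a single seam; a different estimator can be swapped
in without touching the rest of the pipeline.

M-values are `log2(β/(1−β))` with β clamped to `[1e-6, 1 − 1e-6]`: a 5hmC
proportion of exactly 0 is common (the clamp at zero), and the logit must
stay finite. The clamp constant ε = 1e-6 maps 0 to ≈ −19.93; the point mass
this creates for weakly hydroxymethylated CpGs is a real feature of the
estimator and is retained (see Limitations).

A CpG is *systematic* when its 5hmC proportion is ≥ τ = 0.10 in at least
`floor(min_frac · n)` samples with `min_frac = 0.5`. The floor convention
is used because 113 of 227 samples is "at least 50%" only under floor; both
τ and `min_frac` are configurable.

QC order: sample-level exclusion (detection p > 0.01 in more than 2% of
probes) runs before probe-level exclusion (listed cross-reactive/SNP probes;
detection p > 0.01 in more than 1 retained sample), so probe failure counts
reflect retained samples. The order is logged; reversing it changes results
only when a failing probe's failures concentrate in removed samples.

Expression filtering removes genes with CPM < 1 in more than 30 samples,
names containing the case-sensitive substrings LOC/orf/KIAA/NCRNA/MIR, and
sex-chromosome genes, then returns log2(CPM + 1). TMM normalization from
raw reads is out of scope; the synthetic expression is generated directly
on the log2-normalized scale. Expression quartiles are rank-based on
per-gene means with stable input-order tie-breaking; with n not divisible
by 4 the lower quartiles take the extra genes (101 → 26/25/25/25).

## Annotation conventions

Coordinates are 1-based inclusive; BED exports convert to 0-based
half-open at the boundary only. Distances are strand-oriented: upstream
means 5′ of the TSS on the gene's strand and is negative bp; downstream of
the TTS is positive bp; positions inside the gene are the proportion of the
way through it, so `pos = tss` is inside with proportion 0 (flagged choice:
the boundary case is not specified by the convention itself). CGI classes
partition distance-to-island: 0 island, (0, 2 kb] shore, (2 kb, 4 kb]
shelf, > 4 kb open sea, boundaries inclusive toward the island. Raw
compartment labels collapse as TSS200/TSS1500 → TSS and
1stExon/Body/ExonBnd → gene body; a CpG may keep several collapsed labels.
ChromHMM states collapse enhancers + genic enhancers → enhancers,
strong/weak transcription → transcribed, bivalent TSS/enhancer → poised
TSS/enhancers, (weak) polycomb repressed → polycomb repressed; all other
states pass through.

The cis universe pairs a CpG with every gene it is inside, ≤ 1 Mb upstream
of the TSS, or ≤ 1 Mb downstream of the TTS (boundaries inclusive). It is
computed by a sorted-position interval join and is property-tested against
a brute-force double loop.

## The cis scan and the permutation threshold

Per pair, OLS of expression on [1, HM, T] with a two-sided t-test on
`n − k − 2` df. The scan path residualizes both matrices on [1, T] once
(Frisch–Waugh–Lovell) and works with correlations of residuals; this is
algebraically identical to the full OLS t-test and makes the permutation
null affordable. Pairs whose CpG has (numerically) constant M-values are
dropped with a logged count.

Covariate screening: a candidate is kept when it associates (p < 0.05,
simple regression for continuous candidates, one-way ANOVA for categorical)
with at least one of the top five PCs of the M-value matrix *and* at least
one of the top five PCs of the expression matrix. Zero-variance candidates
are skipped with a warning.

Permutations shuffle the expression matrix's sample labels only — one
shuffle per permutation shared by all genes — while 5hmC and covariates
stay fixed, and the shuffled expression is re-residualized on the
covariates. This preserves the HM–covariate structure while breaking the
HM–y link; the per-gene minima remain exchangeable with the observed
minimum under the null. (A flagged alternative — shuffling y and covariates
jointly — is not the default.)

Each gene's 1,000 permutation minima are fitted with a Beta(a, b) by
maximum likelihood: method-of-moments start, damped Newton on (a, b) with
the exact digamma/trigamma gradient and Hessian, iterating to a gradient
sup-norm below 1e-8 (or stalling), always keeping the best-likelihood
iterate so the fit never falls below the moment start. Minima are clamped
to `[1e-12, 1 − 1e-12]` before fitting — a *numerical* clamp only. A
data-scale floor (e.g. 1/(2·n_perm)) was measured to push genuine small
minima upward, thin the fitted left tail, and make gene-level empirical
p-values anti-conservative (false-called genes ≈ 15% of calls instead of
the BH-nominal ≈ 5%); since t-based p-values are never exactly 0 or 1, no
such floor is needed.

The gene's empirical p is the fitted Beta CDF at its observed minimum
nominal p; BH FDR is computed across gene empirical p-values; the empirical
threshold `pt` is the largest empirical p among genes with q < 0.05 (when
no gene is significant there is no threshold and no calls). The call rule
compares each pair's *nominal* p against `pt` and requires gene q < 0.05 —
the literal rule as stated; the GTEx-style per-gene beta-inverted nominal
threshold would be a straightforward alternative behind the same interface.
For every called pair the covariate-free Pearson r between the CpG's
M-values and the gene's expression is attached (the model uses M-values;
betas are available for descriptive plots).

## DHMR scan

Nominal per-pair p-values feed a comb-p-style region caller, run per gene
over that gene's cis probes. z = Φ⁻¹(1 − p). The autocorrelation model is
the Pearson correlation of (z_i, z_j) over probe pairs binned by distance
(250 bp bins up to 1 kb), pooled across genes for stability, floored at 0
to keep the combined-statistic variance positive. Each probe's corrected p
combines its ≤ 1 kb neighbourhood:
`Z = Σ z_j / sqrt(k + 2 Σ_{j<l} ρ(d_jl))`, `p = 1 − Φ(Z)` (an isolated
probe keeps its p; two identical, perfectly correlated probes also do).
Maximal runs of corrected p < 1e-4 with inter-probe gaps ≤ 1 kb become
candidates; the regional p is Stouffer–Liptak over the members' *raw*
p-values (avoiding double combination), Sidak-adjusted with exponent
(span of the gene's tested probe positions) / (region width) — comb-p's
searched-bases convention, made explicit and configurable because it is a
modelling choice, not a printed rule. Significant DHMRs need adjusted
p < 0.05 and ≥ 3 CpGs. Overlapping regions from different genes are
reported per gene, never merged. `max_gap` = 1 kb mirrors the correction
window; it is a configured default, not a claim about the reference tool's
internals.

## Enrichment statistics

The 2×2 enrichment OR is the cross-product (a·d)/(b·c) with a Woolf
(log-OR normal) 95% CI; the exact two-sided p comes from hypergeometric
tail summation. Cross-product is the default because the region-CpG
systematic enrichment reported at study scale (OR 2.96) reproduces from the
reconstructed margins under the cross-product, while R's conditional-MLE
convention differs; the conditional MLE is available via `or_method`. A
zero cell triggers the Haldane–Anscombe +0.5 correction (flagged in the
result). The repeated-measures ANOVA unit is per-sample per-category mean
5hmC (the aggregation level is a documented choice):
`F = MS_condition / MS_(condition×subject)` on (k−1), (k−1)(n−1) df.
Percentages are reported at one decimal (three for the pair-level rate),
matching the precision conventions of the quantities they summarize.

## Synthetic generative model

One synthetic autosome (cis logic is intra-chromosomal under the ±1 Mb
rule). Genes are non-overlapping, 8–60 kb, random strand, placed by stick
breaking with end margins; ~60% of promoters carry a 1 kb CGI plus
intergenic islands; CpGs comprise one guaranteed mid-body CpG per gene,
planted DHMR clusters, a 25% island-weighted share, and uniform background.

Per-CpG true 5hmC means: background from a Beta with mean
`base_hmc_mean = 0.03` and concentration 6 (strongly right-skewed), clipped
to [5e-4, 0.095] so background means stay strictly below the 0.10
systematic threshold; systematic CpGs (fraction 0.068, drawn with open-sea
preference) from a normal around `systematic_hmc_mean = 0.15` (sd 0.03,
clipped to [0.11, 0.35]). Per-sample values are Beta draws around those
means (concentration 30), capped at 1 − 5mC so the noise-free BS beta never
clamps. 5mC means follow CGI class (island 0.08 → open sea 0.65). Betas are
`clip(m5C + 5hmC + ε, 0, 1)` (BS) and `clip(m5C + ε′, 0, 1)` (oxBS) with
independent N(0, 0.02) technical noise. The truth table stores the
float-embedded 5hmC value, so with `noise_sd = 0` the beta-difference
estimator reproduces it bit-exactly, and the recorded systematic flag is
the *realized* classification of the noise-free matrix — the zero-noise
identity is a real pipeline consistency check, not a label tautology.

Covariates (infant sex, birthweight percentile, syncytiotrophoblast
proportion) confound through a shared score — the equally-weighted sum of
their z-scores — which multiplies every CpG's 5hmC mean by
`exp(0.1 · score)` and adds `0.35 · loading_g · score` to every gene's
expression. Equal weights make each covariate in principle detectable by
the PC screen, matching the setting the pipeline emulates (all three
selected). Expression is `N(5, 1.5)` baselines plus covariate terms,
planted effects, and N(0, 1) noise, on the log2-normalized scale.

Planted cis effects add `effect_beta1 × centred M(true 5hmC)` at one
systematic CpG per planted gene. The default `effect_beta1 = 0.8`
expression-units per M-value unit is sized for ≈ 90% power at a
Bonferroni-corrected single-test level over the default cis universe at
n = 200 (required partial correlation ≈ 0.37), *after* accounting for
M-value measurement-error attenuation (λ ≈ 0.73 at the default noise):
the naive sizing without attenuation (0.6) under-delivers. Planted DHMRs
are clusters of 5 CpGs spaced 150 bp inside a gene body whose per-sample
means share a latent factor `f ~ N(0,1)` (mean shift 0.07·f); the target
gene gains `0.9 · f`, sized by simulation so member CpGs show median
per-CpG association p ≈ 1e-6, the regime the region caller is specified
for. Background CpGs are kept ≥ 1.5 kb away from planted clusters so the
planted boundary is unambiguous ground truth; without the buffer the 1 kb
correction window drags adjacent background probes into the called region
(a real smearing property of the method that would make positional
agreement with the planted truth ill-defined).

## What the synthetic data does and does not show

The generator reproduces the features the statistics depend on: right-skew
with a low grand mean, an elevated systematic subset, CGI-dependent
methylation structure, bounded clamped betas with technical noise, shared
covariate confounding, cis-only effects on the M-value scale, and
contiguous correlated regions. It does not emulate probe chemistry (Type
I/II), spatial chip effects, realistic linkage between neighbouring
background CpGs, multi-chromosome genomes, count-level expression noise, or
cell-type mixtures beyond a single summary proportion — so passing tests
demonstrate correctness and calibration of the *procedures*, not
quantitative transferability of any particular OR or count to real
placental data. The study-scale headline counts depend on the original
cohort and are checked only as arithmetic on their printed values.

## Problem sizes used by the tests and the acceptance script

Chosen as the package's own validation scenes: null calibration uses 200
samples × 1,000 genes × 1 CpG/gene × 1,000 permutations (20 replicates in
the test, 1 in the script); eQTHM recovery uses 200 samples, 40 genes,
600 CpGs, 6 planted pairs + 2 planted regions, 1,000 permutations over 20
seeds (5 in the script); DHMR recovery uses 200 samples, 20 genes, 400
CpGs, 1 planted region per replicate. The worked-example arithmetic is
deterministic and seed-independent.

## Known limitations

- The beta-difference estimator is biased upward near zero (clamping a
  noisy difference), visibly inflating the estimated grand mean relative
  to truth; rank-based and threshold-based results are robust to this.
- The beta approximation to permutation minima is an approximation; with
  strongly dependent cis CpGs its far tail can deviate, which is why the
  empirical-threshold machinery is validated by simulation rather than
  assumed.
- The literal threshold rule compares an empirical-p-scale threshold to
  nominal p-values; it is implemented as stated, with the per-gene
  beta-inversion available as an alternative.
- The ANOVA p-value assumes sphericity; no Greenhouse–Geisser correction
  is applied.
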