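# Methods

This note documents the statistical model, the numerical choices, the
synthetic-data generators, and the limits of what the test suite shows.

## The Bernoulli model of splicing and the measurement scale

A cell expressing *n* transcripts of a gene, each independently including a
cassette exon with probability *p*, yields an observed inclusion fraction
with mean *p* and variance *p*(1−*p*)/*n*. Single-cell RT–qPCR measures
each isoform on the threshold-cycle scale; with primers calibrated near
100% efficiency, 2^{E_t} − 1 (E_t = C_max − C_t, C_max = 30 cycles)
approximates the number of template molecules. The inclusion estimate

    p̂ = (2^{E_tI} − 1) / (2^{E_tI} + 2^{E_tS} − 2)

is the binomial ML estimate with n̂ = 2^{E_tI} + 2^{E_tS} − 2 trials. A well
at C_t = C_max encodes non-detection and enters as zero expression, not as
missing; a record in which neither isoform was detected (0/0) is undefined
and excluded. The angular transform t = arcsin √p̂ stabilizes the binomial
variance to ≈ 1/(4n) independent of *p*, so across-cell variance of *t* can
be compared between exons with different inclusion levels. The transform is
the standard square-root (angular) form; a literal arcsin(p) mode exists
behind a flag purely for sensitivity analysis.

## Quality filtering

Filters run in a fixed order (failed wells → optional HKG-based cell
selection → failure-of-expression screening → per-assay LOD), and the
cascade is idempotent.

* **Well QC**: Ct quality must exceed 0.65 and the melt-peak ratio 0.8 —
  both strict inequalities, as the thresholds are printed.
* **Failure-of-expression score**: with I_{x,r} = 1 when assay *x* is
  detected in cell *r* and I_x the assay's detection frequency across
  cells, each undetected well contributes s_{x,r} = I_x, and
  S_r = Σ_x s_{x,r}. Cells whose S_r is an upper outlier by iterated
  one-sided Grubbs (α = 0.05 by default; the underlying study removed two
  such cells by visual inspection, so the formal Grubbs rule here is a
  documented stand-in) are removed. Detection frequencies are computed once
  on the well-filtered plate, not recomputed after each removal.
* **Limit of detection**: per assay, E_t values at or below 8 cycles may be
  noise. Candidate LODs sweep the sorted observed E_t values up to 8;
  values at/below the candidate that one-sided (lower) Grubbs flags against
  the remaining distribution are removed. Sweeping observed values rather
  than a fixed step follows from starting "at the lowest observed" value.
  Constant distributions are a degenerate guard (zero variance ⇒ no
  outlier).
* **Housekeeping-gene selection**: cells are ranked by their maximal
  absolute deviation of HKG expression from the per-gene across-cell
  median, smallest first; ties break on sample id.

Grubbs' test (all three uses) derives its critical value from the
t-quantile formula; the implementation matches published table values to
2e-3 in the tests.

## The gamma location–scale mixed model

The unit of analysis is the unbiased sample variance of *t* for one exon in
one condition across its cells (minimum three cells; exon × condition
groups with no evidence of alternative splicing — all p̂ exactly 0 or all
exactly 1 — are dropped first). Variances are strictly positive and
right-skewed, hence a gamma response:

    y_i ~ Gamma(α, mean μ_i),  log μ_i = x_i'β + b_{g(i)},  b_g ~ N(0, σ_b²)

with fixed effects for conservation (two-level group for qPCR, continuous
score for the RNA-seq branch), mean expression (raw scale by default — the
coefficient's natural magnitude ~1e−5 at qPCR expression scales; a log mode
exists), and condition; and a normal random intercept per cassette exon.
The scale part of the location–scale formulation is an intercept-only
log-shape submodel (a single gamma shape α, estimated on the log scale);
no covariates enter the scale model. Responses carry prior weights
(cells per response divided by the mean across responses) that multiply
their log-likelihood contributions; weights are renormalized to mean one
internally, so fits are invariant to common rescaling. Responses at or
below 1e−12 are excluded (gamma support).

**Estimation.** The marginal likelihood integrates the random intercepts
out with a Laplace approximation: the inner per-group problem is strictly
concave in b (second derivative −α Σ w y/μ − 1/σ² < 0), solved by Newton
with step clipping; the outer optimization over (β, log α, log σ_b) uses
L-BFGS-B with finite-difference gradients. Continuous covariate columns are
standardized internally for conditioning and mapped back afterwards.
Adaptive Gauss–Hermite quadrature with k nodes is available
(`quad_points`); on the study-scale tables it changes coefficients by
~1e−4, so Laplace (k = 1) is the default. The implementation is validated
against three independent oracles: the closed-form two-group balanced case
(an exact multiplicative variance ratio maps to its log on the link scale),
a plain gamma GLM in the σ_b → 0 limit, and R's glmmTMB on a fixture,
which agrees to ≤ 1e−3 in coefficients, random-effect SD and
log-likelihood.

**Inference.** Per-term LRTs compare nested fits, 2Δℓ against chi-square
with the fixed-parameter difference as df; random-effect structure is never
tested. Coefficient p-values use t statistics with residual df = n − p
(the effective df absorbed by the random effects is ignored — a deliberate,
documented simplification). Standard errors come from the numerical
Hessian of the marginal log-likelihood. Residual outliers — normalized
quantile residuals, Φ⁻¹ of the fitted gamma CDF with weight-adjusted shape
— are pruned by iterated two-sided Grubbs with one removal per refit, a
max-iteration guard, and a refusal to empty any factor level. Grubbs on
residuals inherits the classical masking limitation: several gross outliers
can inflate the fitted dispersion enough to hide each other.

**Control comparison.** Log fold changes (single-cell vs diluted-bulk
control) of mean expression and of the variance of *t* are real-valued, so
they are modeled with Gaussian linear mixed models (statsmodels MixedLM,
ML) with group and condition fixed effects (plus the expression fold change
as a covariate in the variance model) and an exon random intercept. A
constant response (e.g. identical experiments) short-circuits to a
degenerate constant fit.

## RNA-seq branch: posterior propagation

PSI inference from short reads is uncertain; per cell the input is S
posterior draws of *p*. One draw of the variance posterior selects,
independently and with replacement, one transformed posterior sample per
cell and takes the unbiased variance across the R cells; the printed
formula in the source material is typographically garbled and is
implemented as this standard R−1-denominator sample variance, which its
structure indicates. 1,000 draws by default (the source says only "many
times"). Summaries are the posterior mean and the central 95% interval.
Refitting the gamma model once per variance draw yields coefficient
posteriors; the minimum-three-cells rule applies per exon × population
before drawing, individual fit failures are dropped, and more than 20%
failures abort the run.

## Synthetic data: what it emulates, and what it does not

The generators reproduce the statistical structure the analysis assumes:

* **Single-cell plates** — per exon, a true inclusion π (uniform on a
  configurable range) and dispersion δ (default U(0.01, 0.05)); per cell, a
  dispersed inclusion uniform on [max(π−δ,0), min(π+δ,1)], a total count n
  from a configurable expression model (default log-normal, median ≈ 1.1e3
  molecules, spanning ~1e2–1e5 — chosen to match the expression-proxy range
  a pre-amplified single-cell assay produces), and k ~ Binomial(n, u).
  Wells report E_t = log2(count + 1) plus additive Gaussian noise on the
  log2 (cycle) scale (default SD 0.25 cycles, a typical qPCR replicate SD);
  E_t below a threshold (default 1.0, i.e. less than one molecule
  equivalent) is emitted as non-detect. Dropout is deterministic
  thresholding rather than a stochastic curve — sufficient to exercise the
  LOD filter, simpler to reason about.
* **Control plates** — δ forced to 0 (replicates share one inclusion
  level), counts scaled down by a dilution factor; only binomial sampling
  and technical noise remain.
* **Conservation profiles** — a per-exon latent level m ~ Beta(1.2, 3)
  (right-skewed, as genome-wide FIR conservation is), the conserved group
  sampling the upper half of the latent distribution; per-side means are m
  plus independent Gaussian jitter (SD 0.05), which induces the strong
  positive upstream/downstream correlation; position scores are Beta
  around the side mean with concentration 8.
* **PSI posteriors** — per cell, Beta(u·d, (1−u)·d) around the dispersed
  inclusion u with pseudo-depth d (mean exactly u, variance u(1−u)/(d+1)),
  so deeper sequencing gives narrower posteriors; u at 0 or 1 degenerates
  to a point mass.

Not emulated: read-level RNA-seq data, melt curves, primer-efficiency
variation, amplification biases correlated across assays, or empirically
calibrated dropout. Passing tests therefore demonstrate correctness of the
*computations* under the stated generative model, not robustness to every
artifact of real plates.

## The null-calibration study

The study design template — 44 exons in two groups of 22, three
conditions, 10–27 cells per exon × condition with the conserved group
deliberately smaller (10–18 vs 17–27), per-cell expression counts
log-uniform on [1e2, 1e5] — is generated deterministically from a fixed
internal seed and stands in for the post-filtering design of the real
assay, whose exact per-exon sample sizes live in supplementary material
not shipped here. Each replicate simulates the no-group-effect generative
model above, builds responses exactly as the real pipeline does, and runs
the group-term LRT with the same fixed effects as the real-data model
(expression and condition included; toggleable). 1,000 replicates run in
about a minute on one CPU; the routine test suite uses a 200-replicate
scaled run with a correspondingly wider Monte-Carlo window. The companion
power mode (per-group δ ranges) verifies the test detects a real effect.

## Known limitations

* Laplace (not full-quadrature) marginal likelihood; differences are
  negligible at study scale but grow for very small groups with large σ_b.
* Residual-df t-tests slightly understate uncertainty when σ_b is large
  relative to the fixed-effect information.
* Grubbs-based screens assume roughly bell-shaped distributions and are
  subject to masking with multiple gross outliers.
* The deposited-data comparisons (Spearman 0.69 on the published exon
  table; the published model coefficients) run only when the user supplies
  the supplementary tables under `data/deposited/`.
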