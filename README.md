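# splicevar

Precision of alternative splicing at the single-cell level: from raw
single-cell RT–qPCR Ct values (or PSI posterior samples from RNA-seq) to
cassette-exon inclusion levels, their across-cell variance, and a weighted
gamma location–scale mixed model quantifying what shapes that variance.

## The scientific problem

A cassette exon is either included in or excluded from each transcript of
its gene. Treating every transcript as an independent Bernoulli trial with
inclusion probability *p* (the inclusion level, PSI), the observed
inclusion fraction in a cell with *n* transcripts has variance
*p*(1−*p*)/*n* — so apparent cell-to-cell variability depends strongly on
both the inclusion level and the expression level. The question this
package's pipeline answers is whether anything *biological* regulates
splicing precision beyond that sampling floor — in particular, whether
exons with evolutionarily conserved flanking intronic regions (FIRs, up to
200 bp of intron on each side) maintain their inclusion levels more
precisely across cells.

The pipeline:

1. **qPCR preprocessing** (`splicevar.qpcr`) — well QC (Ct quality > 0.65,
   melt-peak ratio > 0.8), failure-of-expression scores
   S_r = Σ_x I_x·[Ct_{x,r} = C_max] with iterated Grubbs screening, and a
   per-assay limit of detection found by Grubbs screening of low E_t = C_max
   − C_t values (up to E_t = 8).
2. **Inclusion estimation** (`splicevar.inclusion`) — the ML estimate
   p̂ = (2^{E_tI} − 1)/(2^{E_tI} + 2^{E_tS} − 2), expression proxy
   n̂ = 2^{E_tI} + 2^{E_tS} − 2, and the variance-stabilizing angular
   transform t = arcsin √p̂ with Var(t) ≈ 1/(4n); plus the
   binomial-dispersion chi-square test.
3. **Conservation** (`splicevar.conservation`) — FIR conservation means
   with coding-overlap masking (> 100 bp overlap excludes the exon),
   upstream/downstream Spearman correlation, and tail-based assignment of
   conserved / non-conserved groups.
4. **The variance model** (`splicevar.glmm`, `splicevar.variance`) — the
   across-cell sample variance of t per exon × condition is modeled as
   Gamma with log E[y] = xβ + b_exon, b_exon ~ N(0, σ_b²), weights
   proportional to the number of cells, fit by Laplace-approximated maximum
   likelihood; per-term likelihood ratio tests, Grubbs pruning of residual
   outliers, and Gaussian mixed models for the single-cell vs
   diluted-control comparison.
5. **Posterior propagation** (`splicevar.posterior`) — for RNA-seq, PSI
   posterior draws per cell are resampled into a posterior distribution of
   the across-cell variance, and the gamma model is refit per draw.
6. **Null study** (`splicevar.nullstudy`) — a replicated simulation with no
   group effect verifying that unequal group sizes do not inflate the
   group-effect LRT.
7. **Synthetic data** (`splicevar.synthetic`) — generators for plates,
   control plates, conservation profiles and PSI posteriors with the
   statistical structure above, so the whole pipeline is testable without
   any external data.

## Worked example

`examples/variance_glmm.py` simulates a single-cell experiment in which
conserved-FIR exons have genuinely smaller cell-to-cell dispersion, then
fits the variance model:

```
132 variance responses (44 exons x 3 cell types)
                           coef       se         t        p
Intercept              -5.51048  0.09212 -59.81908  0.00000
group[T.non_conserved]  0.49040  0.07606   6.44777  0.00000
mean_expression        -0.00002  0.00002  -1.12079  0.26449
condition[T.MCF7]      -0.00677  0.07078  -0.09568  0.92392
condition[T.U937]       0.11198  0.07096   1.57813  0.11702
random-intercept SD = 0.165, gamma shape = 9.26
conserved-group effect on log variance: -0.490
LRT for group: statistic=28.89, df=1, p=7.68e-08
```

The conserved-vs-non-conserved contrast of −0.49 on the log link means
conserved exons' variance of transformed inclusion is about e^{−0.49} ≈ 0.6
times that of non-conserved exons, at matched expression and cell type —
the injected effect, recovered. The other examples cover the qPCR filter
cascade, conservation scoring and grouping, the null-calibration study, and
the RNA-seq posterior branch; each prints a line explaining its numbers.

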