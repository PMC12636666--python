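# Methods

`ctfm` implements a context fine-mapping pipeline for GWAS summary
statistics: it scores a library of cis-regulatory annotations for
heritability enrichment with stratified LD-score regression (S-LDSC),
fine-maps the enrichment signal across annotations with a
sum-of-single-effects (SuSiE) model (CT-FM), fine-maps individual risk
variants within 3-Mb regions using functional priors, re-runs context
fine-mapping restricted to the annotations each high-confidence variant
overlaps (CT-FM-SNP), and joins the resulting SNP–context pairs with
SNP-to-gene linking scores into {SNP, context, gene, cancer}
quadruplets.

## Summary-statistics QC and harmonization

Input tables are reduced to a canonical schema (variant, alleles, effect
allele frequency, log-odds beta, SE, p-value, INFO, case/control counts).
The QC cascade removes, in a fixed order so removal attribution is
reproducible: non-autosomal records; multi-allelic physical positions
(any position carrying more than one variant id or more than two distinct
alleles — all records at such a position are dropped, a deliberately
conservative rule since no keep-one rule is well defined); strand-ambiguous
A/T and C/G pairs; INFO < 0.9 (records with *missing* INFO pass, because
several large GWAS report INFO only for a subset of variants; the count
of missing-INFO records is reported); MAF < 0.005; |beta| > 3; p-values
outside (0, 1]; and any residual duplicated position.  The cascade is
idempotent, and `n_input = n_output + sum(removals)` on every input.

Harmonization keeps records matching a panel variant at the same position
with the same unordered allele pair; when the GWAS effect allele is the
panel's non-counted allele, beta is negated and eaf replaced by 1 − eaf.
Records absent from the panel, with panel MAF < 0.005, or with a
GWAS-vs-panel MAF difference above 0.2 are dropped.  Effective sample
size for a case-control GWAS is `1/(1/Ncase + 1/Ncontrol)` in the
chi-squared (LDSC) convention and four times that in the fine-mapping
convention.

## Stratified LD-score regression

Annotation LD scores are `l(j,c) = sum_k a_c(k) r2_adj(j,k)` over a
±1 Mb window, with the small-sample adjustment
`r2_adj = r2 − (1−r2)/(n−2)` applied to squared correlations of
standardized panel dosages.  The regression fits

    E[chi2_j] = intercept + n_eff * (tau_c l(j,c) + sum_b tau_b l(j,b))

one focal context at a time jointly with a base (all-SNPs) column and the
baseline columns — the marginal scan; a joint fit of ~1,500 contexts is
neither stable nor needed for scoring.  A free intercept is estimated by
default (the standard S-LDSC behavior): it absorbs uniform chi-squared
inflation from confounding or from LD attenuation, which matters whenever
the reference panel is small relative to the GWAS.  Weights combine the
heteroskedasticity term `2(1 + n_eff h2 l_tot/M)^2` (with an aggregate
method-of-moments h2 plugged in) and an over-counting factor `1/l_tot`;
an OLS mode is available.  Standard errors come from a leave-one-block-out
jackknife over contiguous equal-count blocks (200 by default, shrunk to
n/10 on small inputs; an explicit block count is honored exactly, so
`n_blocks = n` reproduces the closed-form delete-one jackknife).

The **enrichment z-score** is the jackknife z of the focal coefficient
tau_c conditional on baseline.  The **enrichment statistic** is the share
of fitted per-SNP heritability falling in the annotation divided by its
share of SNPs, with its own jackknife SE.  Degenerate columns (no members
or all-zero LD scores) are flagged rather than fitted.

The **annotation correlation matrix** consumed by context fine-mapping is
the Pearson correlation of context LD-score columns after residualizing
each on the base and baseline columns (OLS with intercept).  Residual
columns with zero variance are flagged and excluded from the
mean-absolute-off-diagonal summary, which serves as the default
credible-set purity threshold (the published library yields ~0.19 for
this quantity; absolute values are used since a purity threshold is a
magnitude).

## The SuSiE engine

One engine serves all three fine-mapping stages, in the z-score (RSS)
parameterization `z ~ N(Rb, R)` with `b = sum_l gamma_l beta_l`: the
"elements" are annotations with the LD-score correlation matrix, or
variants with panel LD.  Each single effect has the standard Bayes
factor `logBF_j = ½ log(1/(1+v)) + (z_j²/2) v/(1+v)`; coordinate ascent
re-fits each of L effects on the residualized z until the ELBO
(sufficient-statistic form, unit residual variance) changes by less than
1e-3 or 100 sweeps.  Numerical choices:

- **Non-PSD R** is eigenvalue-clipped at zero and re-symmetrized;
  correlation matrices of residualized LD scores and sample LD are
  routinely indefinite.
- **Prior variance** defaults to per-effect empirical Bayes (maximize the
  single-effect marginal BF over v ≥ 0, bounded scalar optimization).  An
  effect whose optimum is v = 0 is *inert*: it keeps a uniform alpha row
  and is excluded from PIPs and credible sets, preventing spurious
  uniform PIP inflation.
- **Initialization** is greedy forward selection: each effect is seeded
  at the largest residual z (ties to the lowest index).  Exactly
  symmetric inputs otherwise sit on a saddle point where every effect
  carries an identical split alpha row; the ascent that follows re-derives
  every quantity, so ELBO monotonicity is unaffected.
- **Credible sets**: per active effect, the smallest alpha-descending
  prefix reaching the coverage level (ties broken by element index);
  sets are discarded when the minimum absolute pairwise correlation of
  members falls below the purity threshold; duplicates are dropped;
  singletons have purity 1 by convention.

On problems small enough to enumerate, the engine's PIPs track the exact
posterior of the same model (Bayesian model averaging over all ordered
effect assignments) to within 0.1 when the prior effect variance matches
the signal scale; with a badly misspecified fixed prior variance the
variational fit degrades, which is why the default estimates it.

## CT-FM, SNP fine-mapping, CT-FM-SNP, quadruplets

**CT-FM** restricts to annotations with positive enrichment z, fine-maps
them with L = 10 and uniform priors against the annotation correlation
matrix, and tiers contexts: high-confidence (PIP ≥ 0.5), candidate
(0.05 ≤ PIP < 0.5).  Excluded annotations are reported with PIP 0 so
downstream joins are total.  The purity threshold defaults to the
library-wide mean absolute off-diagonal correlation computed on the full
library, not the positive-z subset.

**SNP fine-mapping** tiles each chromosome with 3-Mb windows stepping by
1.5 Mb (half-overlap guarantees every variant has a window in which it is
within 0.75 Mb of the center; the step is configurable), keeps windows
containing a variant with p < 5e-8 (strict), and fine-maps each with
L = 5, per-SNP priors proportional to externally supplied per-SNP
heritabilities (zero entries floored at 1e-6 of the uniform mass), and a
credible-set purity of 0.5 — the convention of variant-level fine-mapping
tools, distinct from the annotation-level threshold.  Variants analyzed
in several windows keep the result from the window whose center is
nearest (ties toward the lower start).  High-confidence causal variants
have PIP ≥ 0.5.

**CT-FM-SNP** takes each high-confidence variant, collects the
annotations overlapping it that have positive genome-wide z (variants
with fewer than two such annotations are reported but not fine-mapped),
and fine-maps their genome-wide z-scores against the corresponding block
of the annotation correlation matrix with L capped at the block size.
Perfectly correlated annotation pairs are collapsed to a representative.
No candidate tier is used at the variant level.

**Quadruplets** join triplets with PIP ≥ 0.5 to SNP-gene links with
score ≥ 0.5 on the variant; the best-context report keeps, per
(cancer, variant, gene), the context with maximal PIP, ties broken
alphabetically.

## Synthetic data

The generator emulates every input class with known ground truth:

- **Panel**: per chromosome, latent Gaussian sequences with exponential
  autocorrelation `exp(−d/λ)` (an Ornstein–Uhlenbeck chain, exact and
  O(n)) thresholded into haplotypes at MAFs drawn from `maf_range`;
  dosage = sum of two haplotypes.  The latent kernel is positive definite
  by construction.
- **Annotations**: unions of 20-kb segments; each annotation copies
  segments from a shared template with probability `sqrt(c_target)`,
  giving pairwise membership correlation ≈ `c_target`.  A miniature
  baseline (coding-like 1.5%, conserved-like 5%, broad-regulatory 30%
  coverage) plays the role of the large published baseline model.
- **Summary statistics**: per-SNP heritability is proportional to
  `1 + (fold − 1)` inside the causal annotation, normalized to
  `h2_total`.  Causal variants are Bernoulli draws with inclusion
  probability proportional to per-SNP h2 (scale calibrated so the
  expected count equals `n_causal_snps`, capped at 1), and the
  conditional effect variance is `per_snp_h2 / pi` — so unconditionally
  `E[beta²] = per_snp_h2` at every polygenicity and the realized
  enrichment is unbiased.  Marginal z-scores are simulated directly in
  the RSS parameterization, `z = sqrt(n_eff) R beta + eps`,
  `eps ~ N(0, R)` with R the empirical panel LD — the exact regime the
  pipeline operates in; no individual-level phenotypes are produced.
- **Priors and SNP-gene links**: priors are the true per-SNP h2 with
  multiplicative log-normal noise (sd 0.3); causal variants get gene
  links scoring in [0.5, 1), with an equal number of sub-threshold decoys.

Default conditions: 2 chromosomes × 10,000 variants × 500 panel samples ×
40 annotations, one causal annotation at 5-fold enrichment covering ~20%
of the genome, ~1,000 causal variants, h² = 0.5, a 100k/100k case-control
GWAS.  At 10⁴ regression SNPs the enrichment z-score of a truly causal
annotation lands around 3–6 — the same operating range real context
scans report for their top contexts, which is the point of the
calibration: desk-scale inputs should exercise the methods at realistic
signal-to-noise, not realistic per-SNP effect sizes (those would carry no
signal at desk-scale M).

What passing tests do *not* show about real data: the generator has no
recombination-map structure, no allele-frequency/LD coupling, no
population stratification or imputation error, annotation correlations
are exchangeable rather than block-structured by lineage, and the
"population LD" of the simulated GWAS is the panel's own empirical LD.
Recovery rates on synthetic architectures are therefore upper bounds on
robustness, not estimates of real-data performance.

## Problem sizes and check design

The test suite and the acceptance script run everything at the scales
above.  Calibration checks use fixed seed sets: 20 end-to-end seeds for
recovery rates; 40 replicates (4,000 variants each) for jackknife
interval coverage across enrichment levels ≈ {1, 3, 5}; 200 draws
(p = 50, single causal at z ≈ 6) for credible-set coverage; 20 enumerable
problems (p ≤ 8, L = 2) for engine-vs-exact-posterior agreement.
Interval coverage of the enrichment ratio is evaluated against the
*realized* (not expected) enrichment of each replicate, since at these
scales the realized architecture varies substantially around its
expectation; jackknife intervals on a ratio are approximate, so the
accepted band is 85–100% rather than a point value.

## Known limitations

- The marginal (one-context-at-a-time) S-LDSC scan inherits the usual
  caveat: z-scores of correlated contexts are themselves correlated, which
  is exactly what the downstream SuSiE step models, but the pair
  (scan, correlation matrix) is only as good as the baseline adjustment.
- The RSS parameterization records but does not use the fine-mapping
  effective sample size; with in-sample LD and standardized effects this
  is exact, with external panels it shares the usual mismatch caveats of
  summary-statistic fine-mapping.
- Empirical-Bayes prior variances are optimized per effect with no
  refinement pass; heavily correlated designs can retain split PIPs that
  a refinement step would consolidate.
- The enrichment-ratio jackknife SE is unstable when total fitted h² is
  near zero; such intervals are wide and occasionally wild, which the
  coverage band tolerates but a user should expect on weak GWAS.
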