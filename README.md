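# ctfm — context fine-mapping of GWAS heritability

GWAS for cancers (and complex traits generally) implicate hundreds of
mostly non-coding risk variants, but not the cell types, cell lines or
tissues — the *biological contexts* — in which they act.  Stratified
LD-score regression (S-LDSC) can score a library of context-specific
cis-regulatory annotations for heritability enrichment, but because
regulatory programs are shared across contexts, it typically flags many
highly correlated annotations at once, obscuring the drivers.

`ctfm` treats that problem as a fine-mapping problem.  It is a Python
implementation of a cell-type fine-mapping (CT-FM) pipeline for
statistical geneticists working with GWAS summary statistics:

1. **S-LDSC scan** — for each annotation *c*, fit
   `E[χ²_j] = 1 + N·(τ_c ℓ(j,c) + Σ_b τ_b ℓ(j,b))` with baseline columns
   and block-jackknife SEs, yielding an enrichment z-score per
   annotation, where `ℓ(j,c) = Σ_k a_c(k) r²_jk` is the annotation LD
   score from a reference panel.
2. **CT-FM** — apply the sum-of-single-effects (SuSiE) model to the
   vector of positive enrichment z-scores, with the correlation matrix of
   baseline-adjusted annotation LD scores playing the role of LD;
   outputs per-context posterior inclusion probabilities (PIP) and
   purity-filtered 95% credible sets.  Contexts with PIP ≥ 0.5 are
   high-confidence, 0.05 ≤ PIP < 0.5 candidates.
3. **Functionally informed SNP fine-mapping** — SuSiE (L = 5) over
   overlapping 3-Mb windows containing a genome-wide-significant variant
   (p < 5×10⁻⁸), with per-SNP priors proportional to predicted per-SNP
   heritability; variants with PIP ≥ 0.5 are putatively causal.
4. **CT-FM-SNP** — for each causal variant, fine-map only the
   annotations it physically overlaps (those with positive enrichment
   z), producing {SNP, context, cancer} triplets.
5. **Quadruplets** — join high-confidence triplets with high-confidence
   SNP-to-gene linking scores (≥ 0.5) into testable
   {regulatory SNP, context, gene, cancer} hypotheses.

A deterministic synthetic-data generator (`ctfm.simulate`) produces all
inputs — reference panel, BED annotation library, summary statistics,
priors, SNP-gene links — with known causal ground truth, so the entire
pipeline is testable offline.

## Worked example

Simulate a GWAS whose heritability is 5-fold enriched in one of 40
correlated annotations, then run the scan and CT-FM:

```python
from ctfm import SimConfig, effective_sample_size
from ctfm.simulate import (simulate_panel, simulate_annotations,
                           simulate_baseline, simulate_sumstats)
from ctfm.ldscore import (compute_ld_scores, stratified_regression,
                          multiple_testing, annotation_correlation)
from ctfm.contexts import run_ctfm

cfg = SimConfig(seed=7)                     # 10k variants, 40 annotations
panel = simulate_panel(cfg)
library, membership = simulate_annotations(cfg, panel)
_, baseline = simulate_baseline(cfg, panel)
sumstats, truth = simulate_sumstats(cfg, panel, membership)

n_eff = effective_sample_size(cfg.n_case, cfg.n_control, "ldsc")
ld = compute_ld_scores(panel, membership, baseline)
chisq = ((sumstats.beta / sumstats.se) ** 2).to_numpy()
enrichment = multiple_testing(stratified_regression(chisq, ld, n_eff))
corr = annotation_correlation(ld)
contexts = run_ctfm(enrichment, corr, cancer="simulated")

print("truth causal annotation:", truth.causal_annotation_names[0])
print("mean |off-diagonal| LD-score correlation:", round(corr.mean_abs_offdiag, 3))
print(contexts.sort_values("pip", ascending=False).head(3)
      [["annotation", "sldsc_z", "pip", "credible_set_size", "tier"]]
      .to_string(index=False))
```

which prints:

```
truth causal annotation: context_000
mean |off-diagonal| LD-score correlation: 0.188
 annotation  sldsc_z      pip credible_set_size            tier
context_000 3.766799 0.959688                 1 high_confidence
context_038 2.264058 0.014377              <NA>            none
context_037 1.627113 0.004558              <NA>            none
```

The causal annotation attains an enrichment z of 3.8 in the marginal
S-LDSC scan; CT-FM concentrates the posterior on it (PIP 0.96), placing
it alone in a credible set, while the runner-up annotations — which owe
their z-scores to correlated LD scores — drop below PIP 0.02.

The same flow runs from the shell:

```sh
ctfm simulate --seed 7 --out inputs/
ctfm run-all config.yaml           # config points at the files in inputs/
```

`run-all` executes QC → membership → LD scores → enrichment → CT-FM →
SNP fine-mapping → CT-FM-SNP → quadruplets, writing every intermediate
table plus a provenance record into the run directory; an exclusion list
in the config re-runs the context stages on a reduced library for
sensitivity analysis.

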