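# reffree-ewas

Reference-free cell-mixture adjustment for epigenome-wide association
studies (EWAS) on DNA methylation beta values.

## The problem

In a mixed tissue such as whole blood, a phenotype that shifts cell-type
composition shifts methylation at every cell-type-informative CpG, so an
ordinary per-CpG regression confounds *direct* epigenetic effects with
*cell-mediated* ones.  The standard fix projects samples onto reference
methylomes of purified cell types — but reference panels are expensive,
incomplete even for blood, and nonexistent for tissues like placenta or
tumor.  This package estimates the direct effect with **no reference
panel**, for epidemiologists and genomics analysts running EWAS on any
heterogeneous tissue.

## The method

With Y the m×n beta-value matrix and X the n×p design, fit the
unadjusted model Y = B Xᵀ + E by per-CpG OLS, take the thin SVD of the
concatenated matrix [B̃ | Ẽ], keep the d leading left-singular
directions as loadings Λ (they span the cell-type methylation signatures
plus other latent structure), and report the projection residual

    Δ̂ = B̃ − Λ(ΛᵀΛ)⁻¹ΛᵀB̃.

The dimension d is chosen by a random-matrix-theory rule (eigenvalues of
the row-standardized correlation spectrum above the Marchenko–Pastur
edge).  Standard errors come from a beta-scale column bootstrap:
residuals standardized by √(μ(1−μ)), whole sample columns resampled with
replacement (preserving cross-CpG error correlation), rescaled, refit at
the same d.  Per-CpG Wald tests, Storey q-values with π₀, and an
array-wide bootstrap omnibus test complete the inference.  A built-in
generator simulates blood-like mixture-confounded datasets and scores
the estimator against the known truth.  See `docs/methods.md` for the
full model, parameter defaults, and limitations.

## Worked example

`examples/01_fit_direct_effects.py` simulates 500 CpGs × 150 samples in
which the phenotype both shifts blood cell composition and directly
alters 27 CpGs, then runs the full analysis:

```
RMT latent dimension on [B|E]: d = 5
true non-null CpGs: 27 of 500
RMSE vs true direct effect:  adjusted 0.0146   unadjusted 0.0207
estimated proportion of nulls pi0 = 0.91
top 5 CpGs by direct-effect p-value:
  cpg302  delta=+0.1185  se=0.0100  p=2.00e-32  truth=positive
  cpg170  delta=-0.1456  se=0.0154  p=3.42e-21  truth=negative
  cpg218  delta=-0.0727  se=0.0119  p=1.19e-09  truth=negative
  cpg130  delta=+0.0684  se=0.0129  p=1.11e-07  truth=positive
  cpg162  delta=+0.0716  se=0.0147  p=1.07e-06  truth=positive
```

The adjusted estimator recovers the true direct effects with ~30% lower
RMSE than the unadjusted regression, whose slopes at
cell-type-informative CpGs absorb the composition shift; the five most
significant calls are all genuinely non-null loci, with beta-scale
effect sizes (`delta`) and bootstrap standard errors (`se`).

Other examples: dimension selection (`02`), the four-scenario simulation
study (`03`), the omnibus test (`04`), and a file-based analysis driving
the same pipeline as the CLI (`05`).

## Command line

```sh
reffree-ewas fit --methylation beta.tsv --covariates-file samples.tsv \
    --covariate phenotype --bootstrap 250 --seed 0 --out ewas
reffree-ewas simulate --scenario 1 --datasets 100 --seed 0 --out report.json
```

`fit` writes `ewas_results.tsv` (one row per CpG: estimate, SE, z, p, q
per covariate, plus the unadjusted estimate) and `ewas_run.json` (seed,
dimension, replicate count — enough to reproduce the run exactly).

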