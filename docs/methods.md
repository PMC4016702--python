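# Methods

## The problem

An epigenome-wide association study (EWAS) regresses DNA methylation,
measured as beta values (the methylated fraction at a CpG locus, in
[0, 1]), on a phenotype plus covariates, one regression per CpG.  When the
tissue is a cell mixture — blood above all — a phenotype that shifts the
tissue's cell-type composition shifts methylation at every CpG that
distinguishes cell types, producing associations that are real but
mediated entirely by composition.  Reference-based corrections estimate
cell proportions by projecting onto methylomes of purified cell types and
adjust for them; they require a reference panel, which does not exist for
tissues such as placenta or tumor, and may be incomplete even for blood.

This package estimates the **direct effect** Δ — the part of the
phenotype's effect on methylation *not* mediated by cell composition —
with no reference panel at all.

## Model and estimator

Let Y be the m×n beta-value matrix (CpGs × samples) and X the n×p design
(intercept, phenotype, confounders).  The unadjusted model is

    Y = B Xᵀ + E.

Cell mixing is linear on the beta scale: Y = Δ Xᵀ + M Ω ᵀ + error, where
Ω (n×k) holds cell proportions and M (m×k) cell-type mean methylation.
If Ω itself responds linearly to X, the unadjusted coefficients absorb
B = Δ + M Γᵀ and the errors acquire a factor-analytic structure whose
CpG-space loadings span the columns of M.  The same latent loadings
therefore appear in both the coefficient bias and the residual
covariance, which motivates the estimator:

1. fit the unadjusted model by per-CpG ordinary least squares, giving B̃
   and residuals Ẽ;
2. take the thin SVD of the m×(p+n) concatenation [B̃ | Ẽ] — no
   centering or scaling — and keep the d leading left-singular directions
   as a loading matrix Λ = U_d S_d;
3. report the projection residual

       Δ̂ = B̃ − Λ (ΛᵀΛ)⁻¹ Λᵀ B̃.

Δ̂ is invariant to any invertible recombination of Λ's columns, so the
arbitrary rotation/scale of an SVD basis does not matter; the package
exploits this by computing the projection through a thin QR factorisation
of Λ instead of the normal equations.  Analysis must stay on the beta
scale: the logit transform used for M-values destroys the linear-mixing
assumption.  The implementation fixes SVD signs by making the
largest-magnitude entry of each left-singular vector positive so results
are reproducible across linear-algebra backends.

Missing beta values are handled by complete-case OLS per row (each row
must keep at least p+1 observed samples and a full-rank observed design),
by building the SVD from completely observed rows only, and by filling in
loadings for incomplete rows via regression of the row's observed
concatenated entries on the factor matrix.  Fitted means B̃Xᵀ are
materialised at missing positions too, because the bootstrap needs them.

## Choosing the latent dimension d

The default rule uses random matrix theory: standardize each row of
[B̃ | Ẽ] to mean 0 / variance 1, form the (p+n)×(p+n) sample correlation
matrix across rows, and count eigenvalues above the Marchenko–Pastur
upper edge (1 + √(c/m))², the largest eigenvalue a pure-noise matrix of
this shape produces asymptotically.  Rows (not columns) are standardized
because m ≫ p+n; this choice is a documented interpretation of the
standard surrogate-variable RMT recipe and must be kept in mind when
comparing against published dimension estimates for specific datasets.
AIC/BIC selection over truncated-SVD factor models (free-parameter count
m·d + c·d − d²) is included as a comparator; in our experiments BIC
underfits and AIC overfits the simulated structure, consistent with RMT
being the preferred rule.

## Bootstrap inference

The estimator has no usable closed-form variance.  Standard errors come
from a residual bootstrap that respects the beta-value mean–variance
relation (variance ∝ μ(1−μ)):

1. standardize: Ẽ⋆ = Ẽ / √(μ̃(1−μ̃)), with μ̃ the fitted mean clamped
   to [ε, 1−ε], ε = 1e-6 by default (fitted means can leave (0,1) since
   the fit is linear; clamping keeps the scale finite without dropping
   loci);
2. resample whole *columns* of Ẽ⋆ with replacement — this preserves the
   correlation of errors across CpGs, which is what the latent structure
   is made of — and rescale by √(μ̃(1−μ̃)) of the un-resampled means;
3. form Y⋆ = M̂ + rescaled errors (not clipped to [0,1]; the refit is
   linear and clipping would bias means), refit everything at the *same*
   d, and take entrywise standard deviations over R replicates (default
   R = 250).

Missingness travels with resampled columns.  Per-CpG Wald z = Δ̂/SE with
a standard-normal reference (R ≥ 250 makes the normal approximation the
standard choice), Storey q-values with π₀ estimated by the cubic-smoother
rule evaluated at λ = 0.95 (fixed-λ = 0.5 variant available), and an
array-wide omnibus test.  Holding d fixed across replicates reflects
estimation noise at the chosen model; per-replicate reselection is slower
and less stable.

The omnibus statistic is the mean over CpGs of the squared direct effect
of the target covariate (max |Δ̂| available as an alternative).  Null
pseudo-data are bootstrap samples built around fitted means from a refit
*without* the target covariate, so they carry no target effect; the p
value is the exceedance rank (1 + #{T⋆ ≥ T})/(R + 1).  This realization
of the omnibus construction is this package's own design: it controls
type I error at nominal level when the phenotype affects nothing
(measured rate 0.035 at p ≤ 0.05 over 200 null trials), and has high
power against genuine direct effects.  **Limitation:** when the phenotype
shifts cell composition strongly but has no direct effect, the small
mixture leakage that survives projection is itself detected by the global
statistic, and the omnibus test rejects; a significant omnibus p
therefore says "some effect of the covariate survives adjustment", not
"a direct effect exists".

## The synthetic-data generator

The generator emulates a blood-like 450K experiment with m = 1000 CpGs,
n = 250 samples, k = 4 cell types and q = 2 technical array factors.
Four scenarios cross ζ (direct-effect strength) × τ (phenotype→mixture
strength) over {0, 1}.  Fixed once per scenario: intercepts μ_j from an
equal-weight Beta(1.5, 15)/Beta(15, 1.5) mixture (strongly bimodal, modes
near 0.03 and 0.97 as on real arrays); exactly 30 negative / 23 positive
/ 947 null direct slopes, placed with weight ∝ μ(1−μ) so effects sit at
mid-range CpGs, signs drawn to associate negatively with μ, magnitudes
half-normal with scale 0.05·ζ; cell-type deviations M with the first 250
rows (the DMRs) iid Beta(2, 2) rescaled to ±0.4 and all other rows zero.
Per dataset: phenotype x ~ Uniform(0, 1); mixtures Ω_i ~
Dirichlet(40·π_i) with π_i = softmax(log base + τ·(x_i−½)·v), base =
(0.55, 0.25, 0.12, 0.08) and v a fixed unit contrast — concentration 40
gives cell-proportion spreads plausible for whole blood; beta-distributed
biological noise with row dispersions tuned so the mean per-entry
variance is θ = 1e-3 (means clamped to [1e-3, 1−1e-3], with a sanity
guard if more than 5% of entries saturate); and microarray error on the
logit scale — a q = 2 factor structure scaled by 0.1 plus uniqueness
errors of SD 0.25 sharing an exchangeable per-sample component with
ρ = 0.3 so they are correlated across CpGs.  The observed value is
expit(logit(b) + e).

Where the generative parameters are known only qualitatively, the
defaults above were chosen once to be biologically plausible and to
reproduce the magnitude of the published simulation metrics; they are
calibration choices of this package, not published facts.  The "total
effect" truth used for scoring the unadjusted estimator is computed
analytically as Δ plus M times the derivative of the Dirichlet mean
composition with respect to x (averaged over the dataset's samples),
which equals Δ exactly when τ = 0.

What the generator does *not* emulate: probe-type chemistry differences
and normalization artefacts, batch/chip layout effects beyond the generic
factor structure, SNP-affected probes, sex chromosomes, and realistic
genomic autocorrelation of effects.  Passing the simulation suite
therefore shows the estimator recovers direct effects under linear
mixing with factor-structured technical noise — it does not certify
behaviour under normalization failure or annotation error.

## Scenario scoring

`run_scenario` simulates many datasets (100 by default), re-estimates d
by RMT per dataset (typically 6: three mixture degrees of freedom, two
array factors, one shared uniqueness component), and reports

- RMSE(Δ̂ vs Δ), RMSE(B̃ vs Δ), RMSE(B̃ vs total effect), pooled over
  CpGs and datasets;
- SE inflation: median over CpGs of (median-over-datasets SE)/(SD of the
  estimate over datasets), with bootstrap SEs for Δ̂ and classical
  linear-model SEs for B̃.

With mixture confounding present the adjusted estimator roughly halves
the RMSE against Δ; without it, the direct and total targets coincide
and the unadjusted columns are identical by construction.  Default test
problem sizes (100 datasets at full scale without bootstrap; 50 datasets
× 100 replicates for SE calibration; 200 reduced-size trials for the
omnibus size check) were chosen so the full verification suite runs in a
few minutes on one CPU.

## Numerical details and edge cases

- d = 0 is a valid dimension: the projection is the identity and
  Δ̂ = B̃.
- `direct_effects` refuses collinear loadings (rank-deficient Λ at
  working precision) rather than silently regularising.
- Rows with fewer than p+1 observed samples are rejected (a row with no
  residual degree of freedom contributes a degenerate residual).
- Bootstrap replicates that fail to fit are dropped; more than 10%
  failures aborts the run.
- The Beta dispersion in the generator is floored at φ = 1 so rows whose
  clamped means sit at the boundary cannot produce degenerate draws.
- All randomness descends from one master seed through named
  `SeedSequence` streams, so adding a pipeline stage never perturbs
  another stage's draws, and every scenario run is bit-reproducible.

## Known limitations

- The estimator assumes linear mixing on the beta scale; strong
  non-linear technical effects (e.g. severe dye bias surviving
  normalization) violate it.
- The projection removes *all* structure in span(Λ), including any true
  direct effects that happen to align with cell-type signatures; effects
  concentrated at DMRs are attenuated by design.
- Mixture leakage after adjustment is small but non-zero at realistic
  m, n; see the omnibus limitation above.
- q-values treat CpGs as exchangeable tests; after adjustment the tests
  are strongly correlated and π₀ estimates can be conservative.
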