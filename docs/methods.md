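# Methods

This note documents the statistical model, the estimator, the numerical
choices, and the synthetic-data world the test suite runs in — including
what passing tests do and do not establish about real data.

## Measurement model and identification

Every catalog model is a congeneric covariance structure over the 20 PCL-5
items: Σ(θ) = ΛΦΛ′ + Θ, each item loading on exactly one factor, Φ a free
correlation matrix, Θ diagonal. Identification fixes all factor variances
at 1 and leaves every loading free. The marker-item convention would give
identical fit and df; the unit-variance convention was chosen because it
makes loadings directly comparable to standardized reference estimates and
the degrees of freedom transparent: df = p(p+1)/2 − (2·20 + m(m−1)/2),
giving 164/164/160/155/155/149 for the six models.

The combined distress model appends the observed K10 total as a 21st
variable, implemented internally as an extra "factor" with one perfect
indicator: free variance ψ, zero residual, zero covariance with the PTSD
factors, and a free path β_i to every item. Fixing the covariate–factor
covariances to zero is what keeps df at 149 for the 21-variable hybrid
variant (free covariances would consume 7 more parameters); it also gives
β_i the interpretation of the item's distress share *orthogonal* to the
factors. Free parameters: 61 (hybrid) and 82 (combined).

## Estimation

The engine minimizes F_ML(θ) = ln|Σ(θ)| + tr(SΣ⁻¹) − ln|S| − p with
analytic gradients under L-BFGS-B. T_ml = (N−1)·F_ML at the optimum.

Numerical choices:

- **Start values** — loadings 0.5, residual variances 0.5, factor
  correlations 0.3, covariate paths 0.2, each scaled by the variable's
  sample SD so the same starts work for unstandardized inputs (the K10
  total has variance an order of magnitude above the items'). The
  covariate variance starts at its sample value.
- **Bounds** — residual variances ≥ 1e-6 (an active bound is a Heywood
  case and raises a warning rather than silently distorting fit),
  correlations in (−0.999, 0.999), gradient tolerance 1e-8, at most 500
  iterations. Non-PD Σ during the search returns a large penalty value.
- **Tie-breaks/degenerate inputs** — non-PD sample covariance, N ≤ p, and
  df < 0 specs are rejected with descriptive errors; a saturated model has
  no scaling factor by construction.

**Robust correction.** The fourth-moment matrix Γ is the distribution-free
estimator: with centered rows z, Γ is the empirical covariance of the
vectors vech(zz′). The Satorra–Bentler scaling factor is
c = tr(UΓ)/df with U = V − VΔ(Δ′VΔ)⁻¹Δ′V, V the normal-theory weight
matrix 0.5·D′(Σ̂⁻¹⊗Σ̂⁻¹)D at the optimum, and Δ the Jacobian of vech Σ(θ).
T_sb = T_ml/c (the mean-adjusted variant; the mean-and-variance-adjusted
statistic is not implemented). Standard errors are the corresponding
sandwich; standardized loadings and covariate paths get delta-method SEs
via numerical differentiation of the standardization map.

**Fit indices.** CFI and TLI use the robust statistics for both the target
and the structurally-computed independence baseline (df_b = p(p−1)/2, with
its own scaling factor). RMSEA = √(max(T−df,0)/(df·N)) with N (not N−1) in
the denominator — the convention of the software family whose published
values the arithmetic check reproduces (T = 270.061, df = 149, N = 641 →
0.036, CI 0.029–0.042 from the noncentral-χ² inversion at 90%). BIC is the
standard −2·loglik + q·ln N; published model-comparison tables in this
literature sometimes print BIC on an undocumented, much smaller scale, so
BIC enters selection only through differences, never levels.

## Model comparison

Nestedness is decided structurally: model A is nested in B iff B's factor
partition refines A's (A is then B with the correlations between split
factors fixed at 1). Under this rule the DSM-5 and dysphoria models are
non-nested (each splits the other's clusters crosswise), as are anhedonia
and externalizing; all other catalog pairs are nested. The scaled
difference test uses cd = (df₀c₀ − df₁c₁)/(df₀ − df₁) and
TRd = (T_ml,0 − T_ml,1)/cd; a nonpositive cd triggers a warning and an
unscaled fallback recorded in the result (the strictly-positive variant of
the test is deliberately not implemented). Non-nested pairs are decided by
ΔBIC. `select_best` runs all pairs at α = 0.05 and prefers the unique
unbeaten model; conflicting evidence is reported as an explicit tie, never
silently resolved.

## Missing data

Screening tallies respondents by exact number of missing items per
instrument and runs Little's MCAR test (pattern-wise Mahalanobis distances
of observed-variable means under the EM solution). The test's χ²
approximation assumes multivariate normality; on strongly skewed
discretized items (the K10 floor effect) it over-rejects, so a small p on
Likert data is evidence of non-normality at least as much as of MAR. The
calibration test therefore uses normal data, where the rejection rate sits
at the nominal 5%.

Imputation is single conditional-mean imputation under the EM estimate of
(μ, Σ): convergence on the observed-data log-likelihood (tolerance 1e-6,
max 500 iterations, trajectory attached to any failure), observed cells
never altered, imputed values left continuous by default (the estimator
treats items as continuous anyway; `round_to_scale=True` snaps them to the
category range). Variables missing ≥30% trigger a warning. Multiple
imputation and full-information ML are out of scope by design — single
imputation keeps the downstream CFA single-pass.

## Synthetic data: what it emulates, and what it does not

The generator draws correlated unit-variance factors (all pairwise
correlations 0.6 by default — none are published, and 0.4/0.8 sensitivity
values are accepted), an *independent* standard-normal distress score X,
and items λᵢF + βᵢX + eᵢ with unit total latent variance. Defaults are the
reference study conditions: N = 641, the published hybrid loadings (λ) and
distress paths (β), ten K10 indicators on X with loadings 0.65, Likert
discretization through fixed right-skewed thresholds chosen so the PCL
total lands near the reference mean of 26 and the K10 total near 13, and
MCAR masking at the reference per-k rates (e.g. 107/641 respondents
missing exactly 1 PCL item). Same seed → byte-identical output.

Three gaps between this world and real data matter for interpreting tests:

1. **Distress is orthogonal to the factors.** In real samples distress and
   PTSD severity correlate strongly, which is precisely why observed
   attenuation can be large. Under the orthogonal generating model,
   rank-1 contamination is largely absorbed into the factor correlations
   and the attainable loading attenuation is modest — uniform β = 0.4
   contamination flags about 13 of 20 items on average, not all 20, and a
   null world flags essentially none. Test bounds for these properties
   are calibrated from the generator itself.
2. **The covariate is a noisy total.** Partialling the K10 sum rather than
   the latent distress score removes only a reliability-limited share of
   the contamination variance; discretization lowers that share further.
   This is faithful to the analysis design (the real analysis also used
   the observed total) but caps power.
3. **Joint truth is an approximation.** The published before-loadings come
   from the model without the covariate while the distress paths come from
   the combined model; using both as a single generating truth is a
   deliberate simplification. Likewise the simulated K10 total has a
   smaller SD than the reference sample's, because matching its mean,
   floor and variance simultaneously is not possible with equicorrelated
   normal indicators.

Likert discretization attenuates observed-scale loadings relative to the
latent generating values, so parameter-recovery quantities (loading bias,
zero-discrepancy fixed points) are assessed in the continuous
configuration, where the fitted model is exactly correctly specified; the
Likert configuration serves as the non-normality stress test (scaling
factor c > 1, robust statistics).

## Specificity classification

The default attenuation statistic is the difference-form z above, with the
Aroian third product term in the variance; a product-form variant (for the
indirect-effect reading a·b/√(b²s_a² + a²s_b² + s_a²s_b²)) is available as
`aroian_product_z`. The before/after estimates come from the same data and
are positively dependent; the default pools their variances without a
covariance term — matching the information a published loading table
carries — which makes the test conservative. Loadings are compared on the
standardized scale. Multiplicity control defaults to Holm; the
fixed-threshold mode (α/m = 0.0025 at m = 20) is provided because applying
that single threshold to the published 20 attenuation p-values reproduces
the published 13/7 split exactly, while strict Holm on the same rounded
p-values would reject more — both modes are first-class and the pipeline
log states which was used. Factor-correlation before/after comparisons are
reported with the same z machinery but never labeled.

## Problem sizes

Simulation-based checks use: 50 replicates at N = 5000 for the scaling
factor under normality (test suite; 20 in the acceptance script), 200
replicates at N = 641 for the type-I rate of the scaled difference test
(100 in the script), 100 replicates for the selection rate (60 in the
script), 40 replicates for the null-world label rate (30 in the script),
and 20 seeded datasets for the dual-route agreement check against an
independently parameterized brute-force minimizer. These sizes put
Monte-Carlo error well inside the asserted bounds while keeping the full
suite under a minute of compute.

## Known limitations

- Items are treated as continuous under robust ML; no polychoric/WLSMV or
  categorical-ML path, and no FIML for missing data.
- Single imputation understates imputation uncertainty in downstream SEs.
- No multigroup/invariance estimation, bifactor structures, or ICD-11
  symptom subsets.
- The BIC scale of published tables in this literature is not reproducible
  from the definition used here; only BIC differences are meaningful.
- Little's test is anticonservative under strong non-normality (see
  above).
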