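# Methods

## Data model

**Residual activity.** The predictor source is a drug × kinase matrix of
residual activities `A_{k,i} ∈ [0, 1]` from biochemical profiling: the
fraction of kinase *k*'s catalytic activity remaining under drug *i*.
Values are validated to [0, 1] on input; profiling assays occasionally
report small negative baselines or mild activation, and such files must be
clipped upstream before loading.

**Viability and selectivity.** Screens report viability as fraction of
untreated control per cell line; values above 1 (stimulated growth) are
legal, negatives are not. Selectivity is `S = v_N / v_C`; `S > 1` means
the treatment spares the normal line relative to the cancer line. `S` is
undefined at `v_C = 0`, which raises rather than silently clipping —
callers decide how to floor near-zero viabilities.

**Drug pairs.** A pair is unordered; files and in-memory treatments are
canonicalized by sorting the two drug ids, so `(D1, D2)` and `(D2, D1)`
collide as duplicates. The residual activity of a kinase under a pair is
the *product* of the two single-drug activities — the independent-action
assumption. Under the multiplicative viability model this makes a pair's
−log design row the sum of the two drugs' rows, which is what makes pair
screens informative for a linear fit on the −log scale.

## Regression model and transform

Two response models are supported for viability `v_i` of treatment *i*:

* linear: `v_i = β0 + Σ_k β_k A_{k,i}`;
* multiplicative: `v_i = e^{β0_g} · Π_k A_{k,i}^{β_k}` (with a generative
  intercept `β0_g`), fit as the linear regression of `y = −log v` on
  `x_k = −log A_k`.

The −log signs are chosen so both `x` and (for `v ≤ 1`) `y` are
non-negative and a *positive* `β_k` means inhibiting kinase *k* lowers
viability. Activities and viabilities are clipped below at
`ε = 10⁻³` before the logarithm (configurable); the clip bounds design
values at `−log ε ≈ 6.9` and is applied identically by the synthetic
generator, so generated screens satisfy the fitted model exactly at zero
noise.

## Elastic-net solver

The objective, with `M` treatments and unpenalized intercept, is

    F(β0, β) = (1/2M)‖y − β0 − Xβ‖₂² + αρ‖β‖₁ + ½α(1−ρ)‖β‖₂².

Defaults `α = 0.15`, `ρ = 0.01`: a mostly-ridge mix that keeps groups of
correlated kinase predictors (common in kinome profiles, where compounds
hit families) while zeroing clearly irrelevant ones.

The solver is cyclic coordinate descent with exact one-dimensional
updates: `β_j ← S(z_j, αρ)/(c_j + α(1−ρ))` with
`z_j = (1/M)x_jᵀ(r + x_j β_j)`, `c_j = (1/M)x_jᵀx_j`, `S` the
soft-threshold operator, followed by an exact intercept refresh by the
mean residual. Exact coordinate minimization makes `F` non-increasing
across sweeps; convergence is declared when the largest coefficient change
in a sweep (intercept included) drops below `tol` (default `10⁻⁷`, cap
10 000 sweeps — cheap at p ≈ 300, M ≈ 140). Non-convergence is flagged on
the result, not raised. The inner loop is JIT-compiled with numba.

Numerical notes:

* The returned solution carries a KKT certificate
  (`kkt_violation`): `|(1/M)x_jᵀr − α(1−ρ)β_j − αρ·sign(β_j)|` for active
  coordinates, `max(|(1/M)x_jᵀr| − αρ, 0)` for zero ones, and `|mean(r)|`
  for the intercept. The certificate scales with `tol`: at `tol = 10⁻¹²`
  violations sit near machine precision; at the default `10⁻⁷` they are
  of order `10⁻⁷`.
* A zero-variance column with `α(1−ρ) = 0` has an undefined update and is
  held at 0 (minimum-penalty representative).
* Predictors are **not** standardized by default: residual activities
  already share the [0, 1] scale and the objective has no per-column
  scaling term. A `standardize` switch (unit-variance columns, coefficients
  returned on the original scale) is provided for heterogeneous designs.
* Sweeps are cyclic in column order for determinism; a seeded shuffled
  order is available and reaches the same optimum (convex problem).
* Limiting cases are exact: `ρ = 0` matches the ridge closed form
  `(XᶜᵀXᶜ/M + αI)⁻¹Xᶜᵀyᶜ/M` on centered data, `ρ = 1` the lasso, `α = 0`
  OLS.

**Cross-validation.** Leave-one-out: each treatment is predicted from a
fit on the other M−1 (warm-started from the full-data fit for speed;
correctness unaffected by warm starts since the optimum is unique up to
tolerance). Two R² flavours are reported because the label is ambiguous in
common usage: the squared Pearson correlation between held-out predictions
and observations (primary) and `1 − SS_res/SS_tot`. A fold whose training
response is constant predicts that constant. Predictions on the −log scale
invert to viability via `v = exp(−ŷ)`.

## Univariate correlation screen

Per kinase, the Pearson correlation between its activity column and a
response (selectivity or viability) with the two-sided p-value from the
t statistic on M−2 degrees of freedom, then BH-FDR across all non-constant
kinases of the analysis (constant columns have undefined correlation and
are excluded from the FDR family, with a log message). Ties in p are
broken by |r| descending, then symbol, for deterministic output. A kinase
whose inhibition selectively kills the cancer line shows a *negative*
correlation between activity and selectivity.

## Differential ranking and enrichment

Kinases are ranked by the signed difference `β^C − β^N` between the
cancer- and normal-line fits (same kinase order and transform enforced);
large positive values flag kinases whose inhibition costs the cancer line
more viability than the normal line. Selection supports `top_k` and
`min_difference` rules. Published differential tables of this kind list
the *magnitude* |β^C − β^N| (their rows include kinases stronger in the
normal model), so both rules accept a `use_absolute` switch; the signed
difference is the default because the enrichment question — what is
selectively required by the cancer line — is directional.

Enrichment is a one-sided hypergeometric (Fisher exact) upper tail
`P(X ≥ N_S)` computed exactly (no normal approximation): population =
background, successes = pathway members *in the background*, draws =
selected kinases. Conventions, each of which matters for reproducing
published values:

* the background is the assayed kinome (the activity matrix's kinases,
  291 here), not the genome — the selection is all-kinase by construction,
  so a genome background would overstate significance;
* pathway size `N_T` counts only background members (published `N_T`
  values of 4–39 are far below full pathway sizes, so they must be
  kinase-restricted counts);
* pathways with no background member are skipped; BH-FDR runs over the
  tested pathways only;
* gene symbols are matched as trimmed uppercase strings; identifier
  conversion is out of scope (gene sets are consumed from a local GMT).

With 29 selected kinases against a 291-kinase background this convention
reproduces nine of the ten published reference p-values to 3 decimals
(0.008, 0.011, 0.024, 0.026, 0.030, 0.040, 3 × 0.051). The published
axon-guidance row (9 hits in a 31-kinase pathway, printed p = 0.005) is
*not* reproduced — the exact tail gives 0.0012 — and no variant of the
convention we tried (two-sided, different background) yields 0.005 while
preserving the other rows; the discrepancy is documented rather than
forced.

## Synthetic data generator

The generator draws data from the model class the method assumes, which is
the correct surface for desk-scale validation: it answers "does the
implementation recover what the model says it should", not "does the model
hold for real screens".

* **Profiles:** each drug inhibits a Poisson(`targets_per_drug`, default
  15)-sized random kinase subset with activity uniform on (0, 0.5);
  untouched kinases draw from (0.8, 1.0]. This mimics sparse kinome
  profiles at screening doses.
* **Treatments:** `n_drugs` treatments, a `pair_fraction` of them
  unordered random distinct pairs (default all pairs). Random pairing is
  deliberate: an anchor-drug design (one compound in every pair, as
  combination screens often use) makes the anchor's activity pattern
  near-collinear with the intercept and would confound recovery
  assessment.
* **Truth:** each cell line has `n_active_kinases` (default 10) active
  kinases with positive effects of magnitude `true_beta_scale ×
  U(0.5, 1.5)` (default scale 0.5) on the −log scale; the cancer line
  shares half its active set with the normal line and owns the other half
  exclusively, so `β^C − β^N` has a planted answer.
* **Noise:** additive Gaussian (s.d. `noise_sd`, default 0.1) on the −log
  scale, i.e. multiplicative on viability — matching the model class.

Not emulated: kinase-family correlation structure of real profiling
panels, plate/batch effects, dose-response nonlinearity, drug-drug
interactions beyond independent action, and measurement error in the
profiles themselves. Passing recovery tests therefore demonstrates solver
and pipeline correctness on model-consistent data, not predictivity on
real screens.

**Calibration.** At the default study conditions (140 pair treatments,
291 kinases, 10 active, noise 0.1) the calibration run over seeds 0–19
gave a median precision-at-10 of 0.6 for the |β| ranking and a seed-0
LOOCV squared-Pearson R² of 0.855 (−log fit) versus 0.640 (linear); the
frozen test thresholds are median precision ≥ 0.6 and R² > 0.6. Precision
is limited by identifiability, not the solver (which matches an
independent oracle to ~10⁻¹⁰): with ~15 targets per drug an active kinase
is strongly inhibited in only ~10 % of rows, and actives drawn at the low
end of the magnitude range compete with 281 weakly-varying background
columns under a mostly-ridge penalty.

## Scale choices

Tests and the acceptance script run the full 140 × 291 study size (a fit
converges in a few hundred sweeps; LOOCV with warm starts takes ~2 s), 20
replicate screens for recovery, and 30–50 random instances for solver
oracle checks.

## Known limitations

* Exclusion lists (e.g. compounds acting on kinases indirectly) are a
  user-supplied filter, not built in.
* The linear-transform model can predict negative viabilities; the −log
  model cannot, which is one reason it is the default transform.
* LOOCV refits from warm starts; with `tol` loosened far beyond the
  default, fold fits could stop early enough to differ from cold starts.
* No dose handling: profiles and screens are assumed to be at matched,
  fixed concentrations.
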