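# Methods

`cotwin` implements a co-twin control analysis of the association between
educational attainment and dementia, together with a calibrated synthetic-data
generator used to validate every stage against known ground truth.

## The co-twin control model

Twins from the same family serve as each other's controls: monozygotic (MZ)
pairs share all segregating genes and their rearing environment, dizygotic
(DZ) pairs share on average half of segregating genes and the rearing
environment. The exposure (a 3-category education score, `educ3`) is
decomposed for each member *i* of pair *j* into the pair mean
`educ_between_j` and the member's deviation `educ_within_ij`
(`educ_between + educ_within = educ3` exactly; singletons get deviation 0).
The outcome model is a logistic GLMM,

    logit P(Dx_ij = 1) = pi_0j + pi_1 educ_between_j + pi_2 educ_within_ij
                         + pi_3 zyg_j + pi_4 educ_within_ij * zyg_j
                         + pi_5 female_ij + ... + covariates
    pi_0j = gamma_00 + u_0j,   u_0j ~ N(0, sigma^2_{zyg(j)})

with zygosity coded DZ = 1 / MZ = 0 and a pair random intercept whose variance
is estimated separately for MZ and DZ pairs. Under this coding `pi_2` is the
within-pair education effect in MZ twins — the fully familially controlled,
"quasi-causal" effect — and `pi_2 + pi_4` the within effect in DZ twins. A
significant negative `pi_1` with null `pi_2` indicates familial confounding; a
significant `pi_4` attributes it to additive-genetic factors (the DZ within
effect exceeds the MZ one because DZ co-twins share only half their genes),
while a null `pi_4` points to the shared environment. These rules are encoded
in `classify_confounding`, which returns one of `quasi_causal`,
`genetic_confounding`, `shared_env_confounding`, `familial_unspecified`
(zygosity model unavailable) or `no_association`.

Five models form a ladder: (1) raw `educ3` only (total phenotypic effect);
(2) the between/within split; (3) + zygosity main effect and
`educ_within x zyg`; (4) + female main effect; (5) + all female interactions
with the focal terms. Age centred at 60 and study indicators enter every
model; study x female indicators accompany the female main effect (models
4-5), since an interaction without its lower-order term would not be
interpretable.

## Estimation

The marginal likelihood integrates the scalar pair random effect out of each
pair's Bernoulli likelihood with **adaptive Gauss-Hermite quadrature** (AGHQ,
default 15 nodes): nodes are centred at the pair's conditional mode (found by
a safeguarded Newton iteration, vectorized across pairs) and scaled by the
local curvature. With 15 nodes the total log-likelihood of a 10k-pair cohort
agrees with dense brute-force integration to ~1e-4 and a single-pair case to
1e-9; at sigma = 0 the implementation collapses exactly to the ordinary
Bernoulli log-likelihood.

The gradient is computed analytically from the posterior-expectation identity
(the derivative of the log marginal likelihood is the posterior expectation of
the joint score), reusing the quadrature weights; it is verified against
central finite differences in the tests. Optimization is L-BFGS-B on
(fixed effects, log sigma_MZ, log sigma_DZ), started from an ordinary GLM fit
with both variances at 0.5. Termination is gradient-based (projected gradient
1e-7, function tolerance effectively disabled): the variance directions are
nearly flat, and premature function-value stopping was observed to leave
materially different variance estimates at different quadrature sizes, while
gradient-based stopping makes 15- and 25-node fits agree to ~1e-6. Standard
errors come from the inverted observed information, obtained by central
differences of the analytic gradient; Wald z and two-sided normal p-values are
reported per coefficient, and variance-component standard errors use the delta
method on the log scale.

Estimates with |coefficient| > 15 on the link scale raise a separation flag.
Education enters as a numeric 1-3 score (one coefficient per term); dummy
coding of the outcome model was not needed for any reported quantity. A
`fix_variances` option collapses the model to an ordinary GLM/OLS for the
analytic equivalence checks. The `scale_MZ` / `scale_DZ` fields report
per-zygosity Pearson-residual dispersion diagnostics evaluated at the
conditional modes; they are descriptive analogues of the residual-scale block
of pseudo-likelihood software and are not estimated parameters of the
maximum-likelihood fit.

## Synthetic cohorts

`simulate_cohort` draws twin pairs under a bivariate ACE liability model.
Each trait's liability is `a*A + c*C + e*E` with standardized components;
across co-twins A correlates 1 (MZ) or 0.5 (DZ), C is shared, E independent,
so within-pair liability correlations equal `a^2 + c^2` (MZ) and
`0.5 a^2 + c^2` (DZ) exactly in expectation. Confounding between education and
dementia liabilities is induced by the component correlations rA, rC, rE; a
direct liability-scale causal path `beta_causal` adds `beta_causal * edu_liab`
to the dementia liability *without* restandardization (the dementia-liability
variance becomes `1 + beta^2 + 2 beta rho`), because restandardizing would
entangle the path with the variance components.

Phenotypes: the education liability is cut at 8 fixed thresholds into the
9-category ISCED code (defaults give a cohort mean of ~2.9, a predominantly
low/mid-education older population); the LDI score is
`6.5 + 1.2 * (-dem_liab) + N(0, 0.5)` (lower LDI = greater dementia
likelihood, marginal SD ~1.3); dementia is assigned per study stratum either
by a logistic risk model on the liability (clinical/registry strata; includes
age and sex effects, an optional direct log-odds effect `beta_educ3` of the
observed education score, and optional explicit logit-scale pair intercepts)
or deterministically by the LDI cutoff (LDI strata, default cutoff 4.8 ~ 10%
impairment). Onset ages for cases are uniform between 65 and the assessment
age; registry-ascertained cases carry recorded ages 5 years (patient,
outpatient and drug registers) or 7 years (cause-of-death register) above
true onset, which the harmonizer corrects. Opposite-sex pairs are DZ only; sex
enters the risk model but not the ACE structure (no sex-limitation model).
Randomness flows from a single seed through fixed per-stage sub-streams, and
cohorts are byte-identical across runs with the same configuration.

Named scenarios fix the study conditions (all available through
`cotwin.simulate.scenario`, with cohort sizes expressed as a fraction of the
full 29,869-pair / 289-singleton layout):

- **table1_like** — descriptive mixed-ascertainment cohort (60% registry-like,
  25% LDI-like, 15% clinical-like strata), mild genetic and
  shared-environmental confounding (rA = -0.4, rC = -0.2), ~1-5% field-wise
  missingness.
- **null** — no education-dementia association; dementia risk driven by
  explicit logit-scale pair intercepts (sd 1.2 MZ / 0.8 DZ). This is exactly
  the fitted model's null and is used for type-I calibration of the
  within-pair Wald test, which is only meaningful when the null model is
  correctly specified.
- **recovery** — as null plus a direct -0.5 log-odds effect per education
  category, so Model 2's between and within coefficients have a known truth
  on the model's own scale.
- **quasi_causal** — direct -0.5 log-odds effect with liability-driven
  familial clustering of dementia but no cross-trait confounding.
- **genetic_confounding** — rA = -0.8 (education-dementia liabilities
  negatively correlated through additive-genetic factors only), no causal
  path: education appears protective between families while the MZ within
  effect is exactly zero.
- **shared_env_confounding** — rC = -0.8, analogous through the shared
  environment.

ACE defaults (education a2 = 0.4, c2 = 0.35; dementia a2 = 0.6, c2 = 0.1; the
confounding scenarios raise education a2 to 0.6) are illustrative of twin
literature for these traits; no effect-size calibration to any specific cohort
is implied. What the generator does **not** emulate: secular trends and cohort
effects, sex-limitation of the ACE structure, assortative mating, dominance,
non-random participation, differential misclassification of registry
diagnoses, and the internal factor structure of the LDI (it is generated
directly from the dementia liability). Passing tests therefore demonstrate
correctness of the statistical machinery under the stated generative
assumptions, not robustness to those unmodelled features of real consortium
data.

## Harmonization

The 9-category ISCED code collapses to 3 categories (0-2 / 3-5 / 6-8); ages
are capped at 90 and centred at 60; registry onset ages are corrected by -5
(-7 for cause-of-death) years for registry-ascertained cases; dementia is the
clinical diagnosis where available, otherwise LDI < cutoff. Two source
sentences about the LDI threshold orientation conflict; this package follows
"lower LDI indicates greater dementia likelihood", classifying the
strictly-below-cutoff side as demented. Study-specific LDI cutoffs are not
published and are therefore a required configuration input. Records missing
zygosity, ISCED, dementia status or age are flagged with a reason code and
excluded from model fitting but never dropped from the table, so the
flowchart-style accounting (`accounting`, `exclusion_report`) reproduces
exact integer identities (individuals = 2 x pairs + singletons). The
harmonizer is idempotent: derived columns are always recomputed from
preserved raw inputs.

## Discrepant-pair and discordant-pair analyses

Education-discrepant twin pairs (unequal ISCED9, both LDI known) contribute
the within-pair LDI difference LDI(higher educated) - LDI(lower educated),
summarized per pair type with a matched t-test. A comparison set of unrelated
pairs is built by shuffling individuals within exact (sex, birth year) strata
with a seeded RNG, pairing consecutive entries, and re-shuffling (up to 100
attempts) while any pairing is within-family; leftover individuals and
non-discrepant pairings are reported, not fatal. Under pure familial
confounding the expected ordering is |unrelated| > |DZ| > |MZ| ~ 0. Under a
pure causal liability path the *per-unit-ISCED-gap* differences are equal
across pair types while raw differences still scale with the education gap
(MZ pairs have systematically smaller within-pair education gaps); the tests
assert the per-gap form.

Dementia-discordant pairs (exactly one affected, the co-twin observed beyond
the affected twin's onset) are tabulated per study and zygosity as how often
the affected twin had the higher vs the lower education, tested by an exact
two-sided binomial sign test against 0.5 (tail doubling, capped at 1; mid-p
is not used, and equal-education pairs are excluded from the denominator). A
delayed-onset variant also admits both-affected pairs with onset gaps >= 5
years (configurable), treating the later-onset twin as the control.

## Numerical and design choices

- Tie-break in ISCED discretization: category = number of thresholds strictly
  below the liability.
- Degenerate matched t-tests (zero variance) return a flagged result instead
  of raising.
- Classification is a pure function of the coefficient pattern at the stated
  alpha (default 0.05); quasi-causal takes precedence (a significant
  protective MZ-within effect), then familial confounding resolved by the
  interaction, else no association.
- Replicate sizes in the validation tests were chosen by a one-off power
  calibration so that the interaction (or within-effect) Wald power is ~0.99
  at the scenario's effect sizes: ~7.5k pairs per replicate for the
  genetic-confounding verdict (100 replicates), ~13.4k for the quasi-causal
  verdict (20 replicates), 1,000 pairs for type-I calibration (500
  replicates). The verdict-rate floor of 95% reflects the ~2.5% per-replicate
  chance of a spuriously significant protective MZ-within effect at alpha =
  0.05 plus residual interaction-power loss.
- Between-pair education means can optionally be centred at the grand mean
  (`center_between`, default off); this changes only the intercept's
  interpretation.
- The log link is available for log-risk coefficients but is numerically
  fragile near probability 1 and is not used by any validated result.
- The within-pair Wald test is mildly liberal in small cohorts — measured
  rejection rate 0.059 at 1,000 pairs over 1,000 null replicates (only ~half
  of pairs are education-discrepant, so the effective sample for the within
  term is smaller than the pair count) — and exactly nominal (0.050 over 400
  replicates) by 4,000 pairs. This is the usual finite-sample behaviour of
  Wald tests in nonlinear mixed models, not an error in the information
  matrix.

## Known limitations

- The GLMM assumes a normal random intercept; liability-driven scenarios put
  additional non-normal individual-level heterogeneity into the linear
  predictor, so fitted coefficients under those scenarios are
  attenuated relative to the liability-scale generative parameters (the
  signature patterns and their signs are unaffected). Variance-component
  recovery is validated only on exactly-specified data.
- Cases' analysis age is their onset age, as in the emulated design; this
  feedback makes the age coefficient descriptive rather than causal and
  inflates fitted pair variances relative to the generative intercept SDs.
- No survival modelling of onset, no REML, no crossed random effects, no
  missing-covariate imputation, and no meta-analytic pooling beyond the fixed
  study covariate.
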