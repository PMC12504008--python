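# cotwin

Co-twin control analysis of educational attainment and dementia risk.

Low education is a widely cited modifiable dementia risk factor, but the
association may instead reflect *familial confounding*: genes and rearing
environments that shape both how far people go in school and their late-life
dementia risk. The co-twin control design separates these explanations by
using each twin as the matched control for their co-twin — monozygotic (MZ)
pairs share all segregating genes and the rearing environment, dizygotic (DZ)
pairs on average half the genes — so a within-pair education effect that
survives in MZ twins is "quasi-causal", while attenuation patterns across MZ,
DZ and unrelated pairs reveal genetic or shared-environmental confounding.

`cotwin` is aimed at biostatisticians and behavior geneticists who want this
analysis chain as tested, reusable components:

- **`cotwin.simulate`** — bivariate ACE liability-threshold simulator of twin
  cohorts (MZ/DZ same- and opposite-sex pairs, singletons, multiple study
  strata, ordinal ISCED education, a continuous latent dementia index (LDI)
  where lower scores mean greater dementia likelihood, clinical / registry /
  LDI ascertainment, missingness) with known ground truth.
- **`cotwin.harmonize`** — variable-construction rules: ISCED 0–8 collapsed to
  3 education categories, registry onset-age corrections (−5 / −7 years), age
  capping at 90 and centring at 60, dementia = clinical diagnosis or LDI
  cutoff, flowchart-style exclusion flags.
- **`cotwin.glmm`** — the core between-within generalized linear mixed model,
  a scikit-learn-style estimator (`BetweenWithinGLMM`) fitting

      logit P(Dx_ij) = pi_0j + pi_1 Educ_j + pi_2 Educ_ij + pi_3 Zyg_j
                       + pi_4 Educ_ij x Zyg_j + ... ,
      pi_0j = gamma_00 + u_0j,  u_0j ~ N(0, sigma^2_zyg)

  by exact maximum likelihood with adaptive Gauss–Hermite quadrature and
  zygosity-specific random-intercept variances (`Educ_j` = pair mean,
  `Educ_ij` = within-pair deviation, Zyg: DZ = 1).
- **`cotwin.discrepancy`** — within-pair LDI differences for
  education-discrepant pairs, sex/birth-year-matched unrelated comparison
  pairs, matched t-tests.
- **`cotwin.interpret`** — the confounding verdict (quasi-causal / genetic /
  shared-environmental / familial-unspecified / no association) and
  discordant-pair sensitivity analyses with exact sign tests.
- **`cotwin.pipeline` / `cotwin.cli`** — end-to-end orchestration with
  deterministic seeding and sample-accounting reports.

See `docs/methods.md` for the statistical details and design choices.

## Worked example

Simulate a cohort in which education only *appears* protective because the
education and dementia liabilities share additive-genetic factors
(rA = −0.8, no causal path), then fit the model ladder and classify:

```python
from cotwin import (scenario, simulate_cohort, harmonize, fit_bw_glmm,
                    classify_confounding)

ace, cfg = scenario("genetic_confounding", scale=0.1, seed=1)   # ~3k pairs
cohort = harmonize(simulate_cohort(cfg, ace), ldi_cutoff=cfg.ldi_cutoff)
m2 = fit_bw_glmm(cohort, model_id=2)
m3 = fit_bw_glmm(cohort, model_id=3)
print(m3.coef.round(3))
print(classify_confounding(m2, m3).verdict)
```

```
                    estimate     se       z      p
intercept              0.225  0.162   1.392  0.164
educ_between          -1.066  0.082 -13.066  0.000
educ_within           -0.000  0.240  -0.001  0.999
zyg_dz                 0.159  0.125   1.272  0.203
educ_within:zyg_dz    -0.803  0.269  -2.992  0.003
age_c                 -0.024  0.005  -4.490  0.000
genetic_confounding
```

Reading the table: families with higher mean education have much lower
dementia odds (`educ_between` = −1.07 log-odds per category), but within MZ
pairs the better-educated twin is no better off (`educ_within` ≈ 0); the
within effect emerges only in DZ pairs (`educ_within:zyg_dz` = −0.80,
p = 0.003), the signature of additive-genetic confounding — exactly the
mechanism this cohort was generated under, and the pattern the classifier
reports.

The same chain is available from the shell:

```bash
cotwin simulate --scenario genetic_confounding --scale 0.1 --seed 1 --out cohort.csv
cotwin harmonize --in cohort.csv --ldi-cutoff 4.8 --out harm.csv --report acc.txt
cotwin fit --in harm.csv --models 1,2,3,4 --out fits/
cotwin classify --fits fits/
cotwin discrepancy --in harm.csv --seed 1 --out diffs.csv --plot fig.png
cotwin sensitivity --in harm.csv --out sens/
cotwin run-all --seed 1 --out run/        # full pipeline
```

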