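# Methods

## The problem

The predictive validity of a selection test is the correlation between its
scores and a later outcome in the *applicant* population, `r_yx1|a`. In
practice the outcome is observed only in the selected subgroup (the
*incumbents*), and the naïve within-incumbent correlation `r_yx1|i`
understates the validity for two distinct reasons:

1. **Compensatory selection.** When admission is decided by a composite
   `z = w1*x1 + w2*x2`, a deficit on one predictor can be offset by the
   other, so jointly-low applicants are eliminated. This induces a
   negative predictor correlation among incumbents even when the
   applicant-pool predictors are uncorrelated, and the two predictors then
   mutually suppress each other's observed validity.
2. **Range restriction.** Selection compresses the variance of every
   variable correlated with the composite, attenuating all correlations
   involving them.

`validcorr` models the applicant pool as a trivariate normal
`(x1, x2, y)` and estimates `r_yx1|a` from restricted data by four routes,
plus classical-test-theory variants.

## Model and estimators

### Descriptives

All SDs and covariances use the n−1 convention; correlations are Pearson.
The u-ratio is always reported as `SD|applicants / SD|incumbents` — values
below 1 trigger a warning instead of silent inversion, because inputs
quoted from the literature are sometimes printed in the reciprocal
(restricted/unrestricted) sense; the CLI exposes `--invert-u` for exactly
that situation. Applicant-group correlations involving y are computed over
the observed-y rows only and flagged (`y_from_incumbents_only`), never
silently pooled. Zero-variance columns yield flagged-missing correlations,
not zeros.

The semipartial correlation
`r_y(x1.2) = (r_yx1 − r_yx2 r_x1x2) / sqrt(1 − r_x1x2²)` is the
correlation of the outcome with the residual of x1 on x2; it removes the
suppression component and stays in [−1, 1], unlike the beta weight
`β1 = (r_yx1 − r_yx2 r_x1x2)/(1 − r_x1x2²)`.

### Thorndike case A (direct selection)

`r̂_a = u·r_i / sqrt(1 − r_i² + u²·r_i²)`, valid when selection truncated
the studied predictor itself (linearity and homoscedasticity of y on the
predictor). Inside the simulation study the formula is fed, by default,
with the incumbent **semipartial** correlation and the plain u-ratio of
x1 (`StudyConfig.case_a_form="semipartial"`): the suppression artifact is
removed but the indirectness of the selection is still ignored, which is
precisely why the method retains a negative bias that grows as the
selection rate falls. Two variants are provided: `"raw"` (first-order
r_i, plain u) and `"residualized"` (semipartial plus the u-ratio of the
residual of x1 on x2, residuals fit within each group separately). The
residualized variant turns case A into a univariate correction on a
predictor that carries no co-predictor signal and is empirically nearly
unbiased under composite selection — it is the right tool if one *wants*
an unbiased direct-formula estimate, but it is not the default because the
default's purpose here is to quantify the cost of ignoring indirect
selection.

### Thorndike case C (indirect/incidental selection)

With restricted correlations `r_yx1|i`, `r_zx1|i`, `r_zy|i` and the
composite SD ratio `u_z`:

```
r̂_a = [r_yx1|i + r_zx1|i·r_zy|i·(u_z² − 1)]
       / sqrt[(1 + r_zx1|i²(u_z² − 1)) · (1 + r_zy|i²(u_z² − 1))]
```

the classical three-variable (Pearson–Lawley) correction for explicit
truncation of z, exact for normal data when (x1, y) are linear and
homoscedastic on z. It returns `r_yx1|i` unchanged at `u_z = 1` and
coincides algebraically with case A when z *is* x1.

### EM (maximum likelihood)

Outcomes are missing exactly for rejected applicants, and rejection is a
deterministic function of the observed predictors, so the data are MAR
and likelihood inference is valid. EM for the trivariate-normal mean and
covariance with missingness confined to y: the E-step fills
`E[y|x]`, `E[y²|x]` (including the conditional variance) and `E[yx|x]`
for the rejected rows, the M-step recomputes moments. Convergence is
declared when the largest absolute parameter change falls below 1e−8
(scores are on the standard-normal scale, so this is correlation-scale),
capped at 5000 iterations. The convergence factor of EM equals the
fraction of missing information, which approaches 1 at 10% selection;
the iteration cap is then occasionally hit with the parameters already
stable to ~1e−7, and the estimate is returned with `converged=False` and
a warning. Because the pattern is monotone, the ML solution has a closed
form — the Pearson–Lawley multivariate correction (`lawley_oracle`):
regress y on (x1, x2) in incumbents and propagate the plane and residual
variance through the applicant predictor covariance. The oracle uses ML
(1/n) covariance normalization internally so that it is the *exact* EM
fixed point; it exists as an independent cross-check, not as the
implementation path.

### MICE (multiple imputation)

Proper Bayesian normal-linear imputation ("norm"): the regression of y on
(x1, x2) is fit to the observed-y rows; each imputation draws the
residual variance from its scaled inverse-χ² posterior, coefficients from
their conditional normal posterior, and missing y from the posterior
predictive. With one incomplete variable the pattern is monotone and the
chain is at its stationary distribution after one sweep; the default 10
sweeps per chain are independent redraws (kept so the chained structure
is exercised, at trivial cost). Defaults m = 20 imputations. Pooling is
the plain arithmetic mean of the m completed-data correlations, with the
between-imputation SD reported as a diagnostic; Fisher-z pooling is
available (`mice_fit_fisher_z`). Rubin's rules for the pooled variance
are deliberately out of scope — the workflow pools point estimates only.

Because the completed-data correlation is a concave function of the
imputation noise, the pooled mean sits slightly below the ML estimate,
and visibly so when the posterior is wide: at 10% selection the MICE mean
error is ~0.02 more negative than EM's. This is a property of
mean-pooled multiple imputation at severe restriction, not an
implementation artifact, and the method-comparison study reproduces it.

### Classical test theory

`disattenuate(r, rel) = r / sqrt(rel)` with a hard error when the result
would exceed 1. The Hunter–Schmidt stepwise procedure for indirect range
restriction assumes selection acts on the predictor's *true score* and
that measurement-error variance is constant across groups. With
`U = SD_x1|a / SD_x1|i`:

1. `r1 = r_yx1|i / sqrt(rel_y|i)` (criterion unreliability),
2. `rel_x|i = 1 − U²(1 − rel_x|a)` (error variance is unrestricted),
3. `r2 = r1 / sqrt(rel_x|i)` (restricted true-score correlation),
4. case A on the true-score ratio `U_T = U·sqrt(rel_x|a / rel_x|i)`,
5. operational validity = result × `sqrt(rel_x|a)`.

Step 4's `U_T` exceeds `U` because selection compresses true scores more
than observed scores. A generative simulation (true scores with known
correlation, noise per the reliabilities, top-fraction truncation on the
true score) recovers both the true-score correlation and the operational
validity to Monte Carlo accuracy. When selection instead acts on an
error-bearing composite the chain is an approximation; the estimand also
differs from the other methods' (`corr(x1, true-score of y)` rather than
`corr(x1, y)`), so its output is reported separately and never averaged
with them.

## Synthetic data generator

`generate_applicants` draws iid rows from the trivariate standard normal
with the specified correlation matrix (Cholesky); `apply_selection`
computes z, admits the top `ceil(rate·n)` rows (ties broken by stable
input order — measure-zero for continuous scores), and masks y for the
rest. The generator is *random-draw* by default: realized sample
correlations scatter around the population values by ~1/√n, as a real
cohort's would, and the study measures each method against the realized
applicant-sample correlation of its own replication. An
`exact_moments` mode (affine transform to the target sample moments) is
provided for debugging only. Negative composite weights support
reversed scales such as German school grades (1.0 = best).

What the generator does *not* emulate: non-normal score distributions,
self-selection of applicants into the pool, multi-stage admission rules,
or additional unmodelled selection variables. Passing tests therefore
demonstrate correctness under the trivariate-normal MAR model, not
robustness to violations of it.

Closed-form oracles used throughout the tests: for the standard normal
truncated at the top fraction p, the selected-group mean is
`λ = φ(c)/p` with `c = Φ⁻¹(1−p)` and the variance ratio is
`1 − λ(λ−c)`; for independent standard-normal predictors selected on
`z = x1 + x2`, `Var(x1|sel) = (Var(z|sel)+2)/4` and
`Cov(x1,x2|sel) = (Var(z|sel)−2)/4`, giving the incumbent predictor
correlation `(v−2)/(v+2)` with `v = 2·(1−λ(λ−c))` — about −0.64 at 20%
selection.

## Monte Carlo study

`run_study` reruns the scenario (ρ_yx1 = .60, ρ_yx2 = .20, ρ_x1x2 = .00,
N = 1000) for each replication, applies 30/20/10% selection and all four
methods, and summarizes the error `r̂ − r` per cell by mean, SD (n−1),
RMSE = √(mean of squared errors) — bias *included*, and distinguished
from the SD in the output columns — and the empirical 2.5th/97.5th
percentile interval (normal-theory mean±1.96·SD intervals reproduce the
reference bounds less well than percentiles). The error reference
defaults to the realized applicant-sample correlation of each
replication, the quantity the restricted data could at best recover;
population-ρ mode is available and shifts SDs upward by the sampling
variation of the realized correlation (~0.02 at N = 1000).

Seeding: replication i derives `SeedSequence(seed, spawn_key=(i,))`, so
any replication can be regenerated in isolation; the MICE seed for each
(replication, rate) is derived from the same tree. Failed replications
(e.g. a case C domain error) are counted and reported per cell, never
silently dropped; under the default scenario none occur.

Problem sizes: the acceptance-level checks in the test suite run the
study at 300 replications — a scale at which every reference cell is
reproduced within ±0.02 while the whole suite stays fast — and the
examples and the `montecarlo` CLI run the full 1000 replications on
request (`--full` / `--reps 1000`, a few minutes on one CPU).

## Numerical and design choices

- Missing y in CSV: empty field or `NA` accepted on input; written as
  empty. The `selected` flag is inferred as y-present when absent.
- Corrected correlations outside [−1, 1] (possible only through inputs
  that violate the model) are clamped with a logged warning; formulas
  whose denominators become invalid raise instead.
- `CorrelationSpec` validates positive semidefiniteness of the implied
  matrix (eigenvalue ≥ −1e−10) and rejects pools with n < 3.
- EM initializes predictor moments from all rows and y-moments from the
  incumbents; the observed-data log-likelihood is available
  (`report_loglik`) and is non-decreasing across iterations.
- The package is strictly trivariate (one predictor of interest, one
  co-predictor). The two-predictor algebra is explicit everywhere rather
  than hidden behind general k-predictor linear algebra; extension would
  replace `semipartial`/`beta_coefficients` and the composite handling.

## Known limitations

- All corrections inherit the multivariate-normal / linearity /
  homoscedasticity assumptions; none are robustified against violations.
- The Hunter–Schmidt chain is reported as operational validity and the
  step composition follows the constant-error-variance algebra above;
  published applications sometimes compose the steps differently, so
  numerical agreement with any particular published figure is not
  guaranteed or forced.
- MICE pools point estimates only; no Rubin variance, no
  predictive-mean-matching, no missingness in predictors.
- At very small incumbent counts (tens of observed outcomes) the pooled
  MICE estimate is biased toward zero relative to ML (wide-posterior
  nonlinearity); prefer EM there.
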