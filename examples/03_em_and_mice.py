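"""Estimating the unrestricted validity by EM and by multiple imputation.

Treats the rejected applicants' outcomes as missing at random (rejection
depends only on the observed predictors) and estimates the applicant-pool
correlation r_yx1|a two ways: maximum likelihood for the trivariate
normal via EM, and MICE with a proper Bayesian normal imputation model.
The Pearson-Lawley closed form is printed as the analytic cross-check the
EM fixed point must match.
"""

import validcorr as vc

spec = vc.CorrelationSpec(0.60, 0.20, 0.00, 1000)
pool = vc.generate_applicants(spec, seed=3)
sel = vc.apply_selection(pool, vc.SelectionDesign(1.0, 1.0, 0.2))
df = pool.to_dataframe()

em = vc.em_fit(sel)
lw = vc.lawley_oracle(vc.describe(sel, "incumbents"), vc.describe(sel, "applicants"))
mi = vc.mice_fit(sel, vc.MICEConfig(m=20, iterations=10, seed=42))

print(f"realized applicant validity r_yx1|a = {df['x1'].corr(df['y']):.3f}")
print(f"EM   (ML, {em.iterations} iterations)       -> {em.r_hat:.3f}")
print(f"Pearson-Lawley closed form          -> {lw.r_hat:.3f}  (EM fixed point)")
print(f"MICE (m=20, pooled by plain mean)   -> {mi.r_hat:.3f}  "
      f"(between-imputation SD {mi.diagnostics['between_imputation_sd']:.3f})")
print("\n80% of outcomes are missing, yet both estimators recover the pool "
      "correlation\nbecause missingness depends only on the observed predictors (MAR).")
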