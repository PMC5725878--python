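"""Why compensatory selection hides a test's validity.

Draws a 1000-applicant pool in which the admission test (x1) correlates
.60 with later study success (y) while a second criterion (x2) correlates
.20, then admits the top 20% on the composite z = x1 + x2. The admitted
group shows a strongly negative correlation between the two predictors —
each can compensate for the other, so jointly-low applicants are gone —
and the test's within-group validity collapses far below .60. The
semipartial correlation (test residualized on the co-predictor) removes
the suppression part of that collapse; the rest is range restriction.
"""

import validcorr as vc

spec = vc.CorrelationSpec(rho_yx1=0.60, rho_yx2=0.20, rho_x1x2=0.00, n_applicants=1000)
pool = vc.generate_applicants(spec, seed=1)
sel = vc.apply_selection(pool, vc.SelectionDesign(1.0, 1.0, selection_rate=0.2))

df = pool.to_dataframe()
inc = vc.describe(sel, "incumbents")

print(f"applicant pool:   r_yx1|a = {df['x1'].corr(df['y']):.3f}   "
      f"r_x1x2|a = {df['x1'].corr(df['x2']):.3f}")
print(f"admitted (n={inc.n}): r_yx1|i = {inc.r('y', 'x1'):.3f}   "
      f"r_x1x2|i = {inc.r('x1', 'x2'):.3f}   <- selection-induced suppression")

sp = vc.semipartial(inc.r("y", "x1"), inc.r("y", "x2"), inc.r("x1", "x2"))
b1, b2 = vc.beta_coefficients(inc.r("y", "x1"), inc.r("y", "x2"), inc.r("x1", "x2"))
print(f"semipartial r_y(x1.2)|i = {sp:.3f}   (suppression removed; still range-restricted)")
print(f"beta weights: {b1:.3f}, {b2:.3f}   (exceed the first-order correlations)")
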