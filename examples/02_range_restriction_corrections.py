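"""Correcting a restricted validity coefficient with closed formulas.

Applies Thorndike's case A (direct selection) and case C (indirect
selection on the composite) to the incumbent statistics of one simulated
cohort, plus the Hunter-Schmidt classical-test-theory chain when
reliabilities are known. Case A ignores the indirectness of the selection
and lands below the truth; case C recovers it.
"""

import validcorr as vc

spec = vc.CorrelationSpec(0.60, 0.20, 0.00, 10_000)
pool = vc.generate_applicants(spec, seed=2)
sel = vc.apply_selection(pool, vc.SelectionDesign(1.0, 1.0, 0.2))

desc_a = vc.describe(sel, "applicants")
desc_i = vc.describe(sel, "incumbents")
df_a, df_i = sel.to_dataframe(), sel.incumbents()
# the target: validity in the full pool, known here because we simulated it
df_full = pool.to_dataframe()
truth = float(df_full["x1"].corr(df_full["y"]))

# case A fed with the semipartial and the predictor's u-ratio
sp = vc.semipartial(desc_i.r("y", "x1"), desc_i.r("y", "x2"), desc_i.r("x1", "x2"))
u = vc.u_ratio(desc_a, desc_i, "x1")
case_a = vc.thorndike_case_a(sp, u)

# case C uses the explicit selection composite z
case_c = vc.thorndike_case_c(vc.CaseCInputs(
    r_yx1_i=desc_i.r("y", "x1"),
    r_zx1_i=float(df_i["z"].corr(df_i["x1"])),
    r_zy_i=float(df_i["z"].corr(df_i["y"])),
    u_z=float(df_a["z"].std(ddof=1) / df_i["z"].std(ddof=1)),
))

hs = vc.hunter_schmidt_operational(desc_i.r("y", "x1"), u, vc.ReliabilitySpec(0.8, 0.7))

print(f"realized applicant validity r_yx1|a = {truth:.3f}  (the target)")
print(f"restricted r_yx1|i                  = {desc_i.r('y', 'x1'):.3f}")
print(f"case A (semipartial {sp:.3f}, u {u:.3f}) -> {case_a.r_hat:.3f}  (underestimates)")
print(f"case C (u_z {case_c.u_used:.3f})            -> {case_c.r_hat:.3f}  (close to target)")
print(f"Hunter-Schmidt operational validity  = {hs.r_hat:.3f} "
      f"(true-score {hs.diagnostics['true_score_validity']:.3f}; different estimand —\n"
      "  the correlation with the outcome's true score under reliabilities 0.8/0.7)")
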