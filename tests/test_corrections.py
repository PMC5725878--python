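import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import validcorr as vc
from validcorr.types import DomainError


class TestCaseA:
    def test_no_restriction_identity(self):
        assert vc.thorndike_case_a(0.37, 1.0).r_hat == pytest.approx(0.37)

    def test_zero_preserved(self):
        assert vc.thorndike_case_a(0.0, 3.0).r_hat == 0.0

    def test_printed_admission_test_cell(self):
        # semipartial restricted correlation .41, SD ratio quoted reciprocally
        est = vc.thorndike_case_a(0.41, 1 / 0.67)
        assert round(est.r_hat, 2) == 0.56

    def test_hand_arithmetic(self):
        assert vc.thorndike_case_a(0.5, 2.0).r_hat == pytest.approx(1 / np.sqrt(1.75))

    def test_large_sample_direct_truncation(self):
        # bivariate normal rho=.5, top-30% truncation directly on x1
        rng = np.random.default_rng(8)
        n = 200_000
        x1 = rng.standard_normal(n)
        y = 0.5 * x1 + np.sqrt(1 - 0.25) * rng.standard_normal(n)
        t = vc.ApplicantTable.from_arrays(x1, rng.standard_normal(n), y)
        sel = vc.apply_selection(t, vc.SelectionDesign(1.0, 0.0, 0.3))
        inc = sel.incumbents()
        u = np.std(x1, ddof=1) / inc["x1"].std(ddof=1)
        r_i = float(inc["x1"].corr(inc["y"]))
        assert vc.thorndike_case_a(r_i, u).r_hat == pytest.approx(0.5, abs=0.01)

    def test_monotone_in_u_with_unit_limit(self):
        rs = [vc.thorndike_case_a(0.3, u).r_hat for u in (1, 2, 5, 50, 5000)]
        assert all(a < b for a, b in zip(rs, rs[1:]))
        assert rs[-1] == pytest.approx(1.0, abs=1e-3)

    def test_invalid_u_rejected(self):
        with pytest.raises(DomainError):
            vc.thorndike_case_a(0.3, 0.0)


class TestCaseC:
    def test_no_restriction_identity(self):
        est = vc.thorndike_case_c(vc.CaseCInputs(0.37, 0.8, 0.5, 1.0))
        assert est.r_hat == pytest.approx(0.37)

    def test_unrelated_selection_variable_identity(self):
        est = vc.thorndike_case_c(vc.CaseCInputs(0.37, 0.0, 0.0, 1.7))
        assert est.r_hat == pytest.approx(0.37)

    def test_zero_maps_to_zero_and_sign_preserved(self):
        est0 = vc.thorndike_case_c(vc.CaseCInputs(0.0, 0.0, 0.0, 1.5))
        assert est0.r_hat == 0.0
        est = vc.thorndike_case_c(vc.CaseCInputs(0.2, 0.5, 0.4, 1.5))
        assert est.r_hat > 0

    @given(st.floats(-0.95, 0.95), st.floats(0.2, 3.0))
    @settings(max_examples=200, deadline=None)
    def test_coincides_with_case_a_when_z_is_x1(self, r, u):
        # explicit selection on x1 itself: r_zx1=1, r_zy=r, u_z=u
        a = vc.thorndike_case_a(r, u).r_hat
        c = vc.thorndike_case_c(vc.CaseCInputs(r, 1.0, r, u)).r_hat
        assert c == pytest.approx(a, rel=1e-10, abs=1e-10)

    def test_recovers_applicant_correlation_on_large_pool(self, big_selected_pool):
        pool, sel = big_selected_pool
        df_a, df_i = sel.to_dataframe(), sel.incumbents()
        desc_i = vc.describe(sel, "incumbents")
        est = vc.thorndike_case_c(
            vc.CaseCInputs(
                r_yx1_i=desc_i.r("y", "x1"),
                r_zx1_i=float(df_i["z"].corr(df_i["x1"])),
                r_zy_i=float(df_i["z"].corr(df_i["y"])),
                u_z=float(df_a["z"].std(ddof=1) / df_i["z"].std(ddof=1)),
            )
        )
        target = float(pool.to_dataframe()["x1"].corr(pool.to_dataframe()["y"]))
        assert est.r_hat == pytest.approx(target, abs=0.01)

    def test_degenerate_denominator_rejected(self):
        with pytest.raises(DomainError, match="nonpositive"):
            vc.thorndike_case_c(vc.CaseCInputs(0.5, 1.0, 0.5, 1e-9))


class TestClassicalTestTheory:
    def test_disattenuate_trivial_cases(self):
        assert vc.disattenuate(0.3, 1.0) == pytest.approx(0.3)
        assert vc.disattenuate(0.0, 0.5) == 0.0

    def test_disattenuate_arithmetic(self):
        assert vc.disattenuate(0.59, 0.8) == pytest.approx(0.6597, abs=1e-4)

    def test_disattenuate_inconsistent_reliability_rejected(self):
        with pytest.raises(DomainError, match="inconsistent"):
            vc.disattenuate(0.9, 0.5)

    def test_hunter_schmidt_reduces_to_case_a_without_error(self):
        rel = vc.ReliabilitySpec(1.0, 1.0)
        hs = vc.hunter_schmidt_operational(0.41, 1.5, rel)
        assert hs.r_hat == pytest.approx(vc.thorndike_case_a(0.41, 1.5).r_hat)
        assert hs.diagnostics["true_score_validity"] == pytest.approx(hs.r_hat)

    def test_hunter_schmidt_recovers_generative_truth(self):
        # true scores (T, H) with corr .6; x = T + noise (rel .8) and
        # y = H + noise (rel .7); selection truncates the top 20% on T.
        rng = np.random.default_rng(99)
        n = 400_000
        rho, rel_x, rel_y = 0.6, 0.8, 0.7
        t = rng.standard_normal(n)
        h = rho * t + np.sqrt(1 - rho**2) * rng.standard_normal(n)
        x = np.sqrt(rel_x) * t + np.sqrt(1 - rel_x) * rng.standard_normal(n)
        y = np.sqrt(rel_y) * h + np.sqrt(1 - rel_y) * rng.standard_normal(n)
        sel = t >= np.quantile(t, 0.8)
        r_i = float(np.corrcoef(x[sel], y[sel])[0, 1])
        u_x = float(np.std(x, ddof=1) / np.std(x[sel], ddof=1))
        # criterion reliability in the *incumbents*: selection restricts the
        # outcome's true-score variance, so it is below the pool value 0.7
        rel_y_i = rel_y * np.var(h[sel], ddof=1) / np.var(y[sel], ddof=1)
        est = vc.hunter_schmidt_operational(r_i, u_x, vc.ReliabilitySpec(rel_x, rel_y_i))
        # operational validity: corr of observed x with the outcome's true score
        target = float(np.corrcoef(x, h)[0, 1])  # ~ rho * sqrt(rel_x)
        assert est.r_hat == pytest.approx(target, abs=0.01)
        assert est.diagnostics["true_score_validity"] == pytest.approx(rho, abs=0.015)

    def test_hunter_schmidt_inconsistent_inputs_rejected(self):
        with pytest.raises(DomainError, match="reliability"):
            # huge u with low reliability implies negative incumbent reliability
            vc.hunter_schmidt_operational(0.3, 5.0, vc.ReliabilitySpec(0.5, 0.9))
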