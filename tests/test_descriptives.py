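import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import validcorr as vc
from validcorr.types import DomainError


def _table(x1, x2, y, selected=None):
    return vc.ApplicantTable.from_arrays(
        np.asarray(x1, float), np.asarray(x2, float), np.asarray(y, float),
        selected=selected,
    )


class TestDescribe:
    @pytest.mark.parametrize(
        "y, expected",
        [([1, 2, 3], 1.0), ([3, 2, 1], -1.0), ([1, 3, 2], 0.5)],
    )
    def test_small_correlations(self, y, expected):
        t = _table([1, 2, 3], [0, 1, 0], y)
        d = vc.describe(t, "applicants")
        assert d.r("x1", "y") == pytest.approx(expected)

    def test_applicant_y_entries_flagged_when_incomplete(self, selected_pool):
        d = vc.describe(selected_pool, "applicants")
        assert d.y_from_incumbents_only
        assert d.n_y_observed == selected_pool.n_selected
        di = vc.describe(selected_pool, "incumbents")
        assert not di.y_from_incumbents_only
        # y-involving applicant entries equal the incumbent values (same rows)
        assert d.r("y", "x1") == pytest.approx(di.r("y", "x1"))

    def test_correlation_matrix_is_symmetric_unit_diagonal_psd(self, selected_pool):
        d = vc.describe(selected_pool, "incumbents")
        c = d.corr.to_numpy()
        assert np.allclose(c, c.T)
        assert np.allclose(np.diag(c), 1.0)
        assert np.linalg.eigvalsh(c).min() > -1e-10

    def test_zero_variance_column_flagged_not_zeroed(self):
        t = _table([1, 1, 1, 1], [0, 1, 2, 3], [0, 2, 1, 3])
        d = vc.describe(t, "applicants")
        assert d.degenerate == ("x1",)
        assert np.isnan(d.r("x1", "y"))
        assert not np.isnan(d.r("x2", "y"))

    def test_tiny_group_rejected(self):
        t = _table([1, 2], [1, 2], [1, 2])
        with pytest.raises(DomainError, match="n=2"):
            vc.describe(t, "applicants")


class TestURatio:
    def test_unrestricted_group_against_itself_is_one(self, selected_pool):
        d = vc.describe(selected_pool, "applicants")
        assert vc.u_ratio(d, d, "x1") == 1.0

    def test_direct_truncation_matches_closed_form(self):
        # top-20% truncation of a standard normal selected on itself
        rng = np.random.default_rng(11)
        n = 400_000
        x1 = rng.standard_normal(n)
        t = _table(x1, rng.standard_normal(n), rng.standard_normal(n))
        sel = vc.apply_selection(t, vc.SelectionDesign(1.0, 0.0, 0.2))
        u = vc.u_ratio(
            vc.describe(sel, "applicants"), vc.describe(sel, "incumbents"), "x1"
        )
        expected = 1.0 / np.sqrt(vc.truncation_moments(0.2).variance_ratio)  # ~2.14
        assert u == pytest.approx(expected, abs=0.02)

    def test_composite_selection_u_for_x1(self, big_selected_pool):
        # Var(X1 | selected) = (Var(Z | selected) + 2) / 4 for independent
        # standard-normal predictors selected on Z = X1 + X2
        _, sel = big_selected_pool
        u = vc.u_ratio(
            vc.describe(sel, "applicants"), vc.describe(sel, "incumbents"), "x1"
        )
        var_z_sel = 2.0 * vc.truncation_moments(0.2).variance_ratio
        expected = 1.0 / np.sqrt((var_z_sel + 2.0) / 4.0)  # ~1.28
        assert u == pytest.approx(expected, abs=0.01)

    def test_inverted_groups_warn(self, selected_pool):
        da = vc.describe(selected_pool, "applicants")
        di = vc.describe(selected_pool, "incumbents")
        with pytest.warns(UserWarning, match="< 1"):
            vc.u_ratio(di, da, "x1")


class TestSemipartialAndBeta:
    def test_no_suppression_identity(self):
        assert vc.semipartial(0.37, 0.5, 0.0) == pytest.approx(0.37)

    @pytest.mark.parametrize(
        "r1, r2, r12, expected",
        [
            # values solved from the printed suppression decompositions
            (0.37, -0.124, -0.71, 0.40),
            (0.39, -0.06, -0.47, 0.41),
            (-0.06, 0.39, -0.47, 0.14),
        ],
    )
    def test_suppression_decompositions(self, r1, r2, r12, expected):
        assert vc.semipartial(r1, r2, r12) == pytest.approx(expected, abs=0.005)

    def test_beta_hand_case(self):
        b1, b2 = vc.beta_coefficients(0.5, 0.5, -0.5)
        assert (b1, b2) == (pytest.approx(1.0), pytest.approx(1.0))

    def test_beta_orthogonal_reduces_to_correlations(self):
        assert vc.beta_coefficients(0.4, 0.1, 0.0) == (
            pytest.approx(0.4), pytest.approx(0.1)
        )

    def test_collinear_rejected(self):
        with pytest.raises(DomainError, match="collinear"):
            vc.semipartial(0.3, 0.3, 1.0)
        with pytest.raises(DomainError, match="collinear"):
            vc.beta_coefficients(0.3, 0.3, -1.0)

    @given(
        st.floats(-0.99, 0.99), st.floats(-0.99, 0.99), st.floats(-0.95, 0.95)
    )
    @settings(max_examples=200, deadline=None)
    def test_beta_equals_scaled_semipartial(self, r1, r2, r12):
        sp = vc.semipartial(r1, r2, r12)
        b1, _ = vc.beta_coefficients(r1, r2, r12)
        assert b1 == pytest.approx(sp / np.sqrt(1 - r12**2), rel=1e-10, abs=1e-10)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=50, deadline=None)
    def test_semipartial_bounded_for_valid_triples(self, seed):
        # draw a correlation triple from a genuinely PSD random matrix
        rng = np.random.default_rng(seed)
        a = rng.standard_normal((3, 5))
        c = np.corrcoef(a)
        r1, r2, r12 = c[0, 2], c[1, 2], c[0, 1]
        if abs(r12) > 0.999:
            return
        assert abs(vc.semipartial(r1, r2, r12)) <= 1.0 + 1e-12


class TestResidualize:
    def test_perfect_fit_gives_zero_residuals(self):
        t = _table([1, 2, 3, 4], [1, 2, 3, 4], [0, 0, 1, 1])
        res = vc.residualize(t, "x1", "x2", "applicants")
        np.testing.assert_allclose(res, 0.0, atol=1e-12)

    def test_uncorrelated_covariate_keeps_sd(self):
        rng = np.random.default_rng(3)
        x1 = rng.standard_normal(5000)
        x2 = rng.standard_normal(5000)
        t = _table(x1, x2, rng.standard_normal(5000))
        res = vc.residualize(t, "x1", "x2", "applicants")
        assert res.std(ddof=1) == pytest.approx(x1.std(ddof=1), rel=0.01)

    def test_hand_computed_fixture(self):
        # x1 = 1 + 2*x2 except one perturbed point (+1 at x2=2)
        x2 = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
        x1 = 1.0 + 2.0 * x2
        x1[2] += 1.0
        t = _table(x1, x2, np.zeros(5))
        res = vc.residualize(t, "x1", "x2", "applicants").to_numpy()
        # OLS of x1 on x2: slope 2, intercept 1.2 -> residuals (-0.2,-0.2,0.8,-0.2,-0.2)
        np.testing.assert_allclose(res, [-0.2, -0.2, 0.8, -0.2, -0.2], atol=1e-12)

    def test_residuals_uncorrelated_with_covariate(self, selected_pool):
        res = vc.residualize(selected_pool, "x1", "x2", "incumbents")
        inc = selected_pool.incumbents()
        assert abs(np.corrcoef(res, inc["x2"])[0, 1]) < 1e-10
        assert abs(res.mean()) < 1e-10

    def test_constant_covariate_rejected(self):
        t = _table([1, 2, 3], [5, 5, 5], [1, 2, 3])
        with pytest.raises(DomainError, match="constant"):
            vc.residualize(t, "x1", "x2", "applicants")
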