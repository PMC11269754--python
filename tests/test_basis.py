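"""Shifted Vieta-Lucas basis: values, coefficients, roots, projections, bounds."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fsvlf import (
    BasisParams,
    basis_matrix,
    explicit_coefficients,
    fsvlf_roots,
    fsvlf_value,
    project,
    svlf_value,
    theoretical_bounds,
)


class TestPointValues:
    @pytest.mark.parametrize(
        "k, r, expected",
        [
            (0, 0.3, 2.0),          # degree 0 is the constant 2
            (1, 0.25, -1.0),        # 4r - 2
            (2, 0.25, -1.0),        # printed explicit form 2 - 16r + 16r^2
            (3, 0.0, -2.0),         # V_k(0) = 2 cos(k pi) = 2(-1)^k
            (4, 0.0, 2.0),
            (7, 1.0, 2.0),          # V_k(1) = 2 for every k
        ],
    )
    def test_recurrence_values(self, k, r, expected):
        assert svlf_value(k, r) == pytest.approx(expected, abs=1e-14)

    def test_matches_chebyshev_form(self):
        # V_k(r) = 2 T_k(2r - 1): the trigonometric closed form
        rs = np.linspace(0, 1, 23)
        for k in range(9):
            expected = 2 * np.cos(k * np.arccos(2 * rs - 1))
            assert np.allclose(svlf_value(k, rs), expected, atol=1e-12)

    def test_negative_degree_rejected(self):
        with pytest.raises(ValueError):
            svlf_value(-1, 0.5)

    def test_fractional_reduces_to_plain_at_alpha_one(self):
        rs = np.linspace(0, 1, 11)
        for k in range(7):
            assert np.allclose(fsvlf_value(k, 1.0, rs), svlf_value(k, rs))

    @pytest.mark.parametrize(
        "k, alpha, r, expected",
        [(1, 0.5, 0.25, 0.0), (5, 1.7, 1.0, 2.0)],
    )
    def test_fractional_values(self, k, alpha, r, expected):
        assert fsvlf_value(k, alpha, r) == pytest.approx(expected, abs=1e-14)

    def test_bounded_by_two(self):
        rs = np.linspace(0, 1, 2001)
        for alpha in (1.0, 1.7):
            for k in range(13):
                assert np.max(np.abs(fsvlf_value(k, alpha, rs))) <= 2.0 + 1e-12


class TestExplicitCoefficients:
    @pytest.mark.parametrize(
        "k, expected",
        [
            (0, [2.0]),
            (2, [2.0, -16.0, 16.0]),
            (3, [-2.0, 36.0, -96.0, 64.0]),
        ],
    )
    def test_printed_forms(self, k, expected):
        assert explicit_coefficients(k).tolist() == expected

    def test_agrees_with_recurrence(self):
        # recurrence is the independent oracle for the factorial formula
        rng = np.random.default_rng(0)
        rs = rng.uniform(0, 1, 100)
        for k in range(13):
            c = explicit_coefficients(k)
            poly = rs[:, None] ** np.arange(k + 1) @ c
            scale = np.max(np.abs(c))
            assert np.allclose(poly, svlf_value(k, rs), atol=1e-9 * scale)

    def test_negative_degree_rejected(self):
        with pytest.raises(ValueError):
            explicit_coefficients(-2)


class TestBasisMatrix:
    def test_K1(self):
        N = basis_matrix(BasisParams(K=1))
        assert N.tolist() == [[2.0, -2.0], [0.0, 4.0]]

    def test_first_row_alternates(self):
        N = basis_matrix(BasisParams(K=9))
        assert np.allclose(N[0], 2.0 * (-1.0) ** np.arange(10))

    def test_monomial_row_reproduces_fsvlf(self):
        params = BasisParams(K=6, alpha=1.7)
        N = basis_matrix(params)
        rng = np.random.default_rng(1)
        for r in rng.uniform(0, 1, 20):
            row = r ** params.exponents @ N
            expected = [fsvlf_value(k, 1.7, r) for k in range(7)]
            assert np.allclose(row, expected, atol=1e-12)

    def test_upper_triangular(self):
        N = basis_matrix(BasisParams(K=8))
        assert np.allclose(np.tril(N, -1), 0.0)


class TestRoots:
    def test_closed_forms(self):
        assert fsvlf_roots(1).tolist() == [0.5]
        assert np.allclose(fsvlf_roots(2), [0.5 - math.sqrt(2) / 4, 0.5 + math.sqrt(2) / 4])

    @pytest.mark.parametrize("alpha", [1.0, 1.7])
    def test_roots_annihilate_and_lie_inside(self, alpha):
        for k in range(1, 11):
            roots = fsvlf_roots(k, alpha)
            assert len(roots) == k
            assert np.all((roots > 0) & (roots < 1))
            assert np.all(np.diff(roots) > 0)
            for r in roots:
                assert abs(fsvlf_value(k, alpha, float(r))) < 1e-10

    def test_alpha_scaling(self):
        # exponent 1/alpha: alpha=2 roots are square roots of the alpha=1 roots
        assert np.allclose(fsvlf_roots(5, 2.0), np.sqrt(fsvlf_roots(5, 1.0)))

    def test_degree_zero_rejected(self):
        with pytest.raises(ValueError):
            fsvlf_roots(0)


class TestProjection:
    def test_constant(self):
        pr = project(lambda r: 2.0, BasisParams(K=4, alpha=1.3))
        assert pr.beta[0] == pytest.approx(1.0, abs=1e-12)
        assert np.max(np.abs(pr.beta[1:])) < 1e-12
        assert pr.eta.tolist() == [4.0, 2.0, 2.0, 2.0, 2.0]

    @pytest.mark.parametrize("alpha", [1.0, 1.7])
    def test_orthogonality_recovers_basis_member(self, alpha):
        pr = project(lambda r: fsvlf_value(3, alpha, r), BasisParams(K=5, alpha=alpha))
        assert pr.beta[3] == pytest.approx(1.0, abs=1e-10)
        others = np.delete(pr.beta, 3)
        assert np.max(np.abs(others)) < 1e-10

    @pytest.mark.parametrize("alpha", [1.0, 1.7])
    def test_orthogonality_integrals(self, alpha):
        # weighted inner products equal (pi/alpha) * {0, 2, 4}
        n = 4096
        s = (np.arange(n) + 0.5) * np.pi / n
        r = (0.5 * (1 + np.cos(s))) ** (1 / alpha)
        for k in range(9):
            vk = fsvlf_value(k, alpha, r)
            for k2 in range(k, 9):
                ip = np.sum(vk * fsvlf_value(k2, alpha, r)) * (np.pi / n) / alpha
                target = (np.pi / alpha) * (4.0 if k == k2 == 0 else 2.0 if k == k2 else 0.0)
                assert ip == pytest.approx(target, abs=1e-8)

    def test_exact_on_span(self):
        # a degree-K polynomial in r^alpha is reproduced exactly
        params = BasisParams(K=5, alpha=1.7)
        rng = np.random.default_rng(3)
        coeffs = rng.normal(size=6)

        def g(r):
            return coeffs @ r ** params.exponents

        pr = project(g, params)
        rs = np.linspace(0, 1, 200)
        assert np.max(np.abs(pr.reconstruct(params, rs) - [g(r) for r in rs])) < 1e-10

    def test_exponential_coefficient_decay(self):
        # |beta_k| < 4 M / (pi k^4) with M = max|g''| = e on [0, 1]
        params = BasisParams(K=16, alpha=1.0)
        pr = project(math.exp, params)
        for k in range(2, 17):
            assert abs(pr.beta[k]) < 4 * math.e / (math.pi * k**4)


class TestBounds:
    def test_closed_form_value(self):
        rep = theoretical_bounds(math.e, 4)
        assert rep.coeff_bounds[2] == pytest.approx(4 * math.e / (16 * math.pi), rel=1e-12)

    def test_sup_bound_scaling(self):
        a, b = theoretical_bounds(1.0, 4), theoretical_bounds(1.0, 8)
        assert a.sup_tail_bound / b.sup_tail_bound == pytest.approx(8.0, rel=1e-12)
        assert a.l2_tail_bound > b.l2_tail_bound
        assert a.consecutive_bound > b.consecutive_bound

    def test_degenerate_linear_function(self):
        rep = theoretical_bounds(0.0, 4)
        assert rep.sup_tail_bound == rep.l2_tail_bound == rep.consecutive_bound == 0.0

    @pytest.mark.parametrize("K", [4, 8, 16])
    def test_sup_norm_truncation_bound_for_exponential(self, K):
        # dense-grid truncation error stays under 8 M / (3 pi K^3)
        params = BasisParams(K=K, alpha=1.0)
        pr = project(math.exp, params)
        rs = np.linspace(0, 1, 1000)
        err = np.max(np.abs(pr.reconstruct(params, rs) - np.exp(rs)))
        assert err < 8 * math.e / (3 * math.pi * K**3)


@settings(deadline=None, max_examples=50, derandomize=True)
@given(
    k=st.integers(min_value=0, max_value=10),
    r=st.floats(min_value=0.0, max_value=1.0, allow_nan=False),
    alpha=st.floats(min_value=0.3, max_value=3.0, allow_nan=False),
)
def test_fractional_value_is_substitution(k, r, alpha):
    """V^alpha_k(r) is exactly V_k(r**alpha), and never exceeds 2 in magnitude."""
    v = fsvlf_value(k, alpha, r)
    assert v == pytest.approx(svlf_value(k, r**alpha), abs=1e-12)
    assert abs(v) <= 2.0 + 1e-12
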