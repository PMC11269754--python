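"""Shifted Vieta-Lucas functions and their fractional-order generalization.

The shifted Vieta-Lucas functions (SVLFs) ``V_k`` live on [0, 1] and are the
image of the Vieta-Lucas polynomials on [-2, 2] under the affine map
``s = 4r - 2``; equivalently ``V_k(r) = 2 cos(k arccos(2r - 1))``, i.e. twice a
shifted Chebyshev polynomial of the first kind.  The fractional-order family
(FSVLFs) substitutes ``r -> r**alpha`` so the basis spans the fractional
monomials ``r**(l*alpha)``, ``l = 0..K``.  This module provides point values,
exact monomial coefficients, the change-of-basis matrix, roots (the collocation
nodes), weighted orthogonal projections and the closed-form convergence bounds
of the truncated expansion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "BasisParams",
    "ProjectionResult",
    "BoundReport",
    "svlf_value",
    "fsvlf_value",
    "explicit_coefficients",
    "basis_matrix",
    "fsvlf_roots",
    "project",
    "theoretical_bounds",
]


@dataclass(frozen=True)
class BasisParams:
    """Truncation degree and fractional exponent of an FSVLF family.

    The truncated series has ``K + 1`` terms and spans
    ``{r**(l*alpha) : l = 0..K}`` on [0, 1].
    """

    K: int
    alpha: float = 1.0

    def __post_init__(self) -> None:
        if self.K < 0:
            raise ValueError(f"K must be nonnegative, got {self.K}")
        if self.alpha <= 0:
            raise ValueError(f"alpha must be positive, got {self.alpha}")

    @property
    def n_terms(self) -> int:
        return self.K + 1

    @property
    def exponents(self) -> np.ndarray:
        """Monomial exponents ``l * alpha`` of the underlying fractional powers."""
        return self.alpha * np.arange(self.K + 1, dtype=float)


@dataclass
class ProjectionResult:
    """Coefficients of a weighted orthogonal projection onto the FSVLF span.

    ``beta[k]`` multiplies the degree-k FSVLF; ``eta`` are the normalization
    constants of the orthogonality relation (eta_0 = 4, eta_k = 2 otherwise).
    """

    beta: np.ndarray
    eta: np.ndarray
    quadrature_nodes: int

    def reconstruct(self, params: BasisParams, r) -> np.ndarray:
        """Evaluate the truncated series sum_k beta_k V^alpha_k(r)."""
        r = np.asarray(r, dtype=float)
        out = np.zeros_like(r)
        for k, b in enumerate(self.beta):
            out = out + b * fsvlf_value(k, params.alpha, r)
        return out


@dataclass
class BoundReport:
    """Closed-form decay and truncation-error bounds of an FSVLF expansion.

    For a twice continuously differentiable function with
    ``M_inf = max |g''|`` on [0, 1] (and alpha = 1):

    - ``coeff_bounds[k]``: |beta_k| < 4 M_inf / (pi k^4) for k >= 2,
    - ``l2_tail_bound``: weighted-L2 norm of the tail, sqrt(8/(7 pi)) M_inf K^(-7/2),
    - ``sup_tail_bound``: sup-norm of the tail, 8 M_inf / (3 pi) K^(-3),
    - ``consecutive_bound``: weighted-L2 gap between successive truncations,
      2 sqrt(2) M_inf / sqrt(pi) K^(-4).
    """

    M_inf: float
    K: int
    coeff_bounds: np.ndarray = field(repr=False)
    l2_tail_bound: float = 0.0
    sup_tail_bound: float = 0.0
    consecutive_bound: float = 0.0


def svlf_value(k: int, r):
    """Value of the shifted Vieta-Lucas function of degree ``k`` at ``r``.

    Uses the three-term recurrence seeded with V_0 = 2, V_1 = 4r - 2:
    ``V_{k+1}(r) = (4r - 2) V_k(r) - V_{k-1}(r)``.
    """
    if k < 0:
        raise ValueError(f"degree k must be nonnegative, got {k}")
    r = np.asarray(r, dtype=float)
    v_prev = np.full_like(r, 2.0)
    if k == 0:
        return v_prev if v_prev.ndim else float(v_prev)
    v = 4.0 * r - 2.0
    for _ in range(1, k):
        v, v_prev = (4.0 * r - 2.0) * v - v_prev, v
    return v if v.ndim else float(v)


def fsvlf_value(k: int, alpha: float, r):
    """Value of the fractional SVLF ``V^alpha_k(r) = V_k(r**alpha)``."""
    if alpha <= 0:
        raise ValueError(f"alpha must be positive, got {alpha}")
    r = np.asarray(r, dtype=float)
    if np.any((r < 0) | (r > 1)):
        raise ValueError("r must lie in [0, 1]")
    return svlf_value(k, r**alpha)


def explicit_coefficients(k: int) -> np.ndarray:
    """Exact monomial coefficients of the degree-k SVLF.

    Returns ``c`` with ``V_k(r) = sum_l c[l] r**l`` where, for k >= 1,
    ``c[l] = 2k (-1)**(k-l) 4**l (k+l-1)! / ((k-l)! (2l)!)``; the degree-0
    function is the constant 2.  In the fractional family the same
    coefficients attach to ``r**(l*alpha)``.  The factorial ratio is formed in
    exact integer arithmetic (coefficients reach ~1e9 by k = 12) before the
    conversion to float.
    """
    if k < 0:
        raise ValueError(f"degree k must be nonnegative, got {k}")
    if k == 0:
        return np.array([2.0])
    coeffs = []
    for ell in range(k + 1):
        num = 2 * k * 4**ell * math.factorial(k + ell - 1)
        den = math.factorial(k - ell) * math.factorial(2 * ell)
        c = (-1) ** (k - ell) * (num // den)
        coeffs.append(float(c))
    return np.array(coeffs)


def basis_matrix(params: BasisParams) -> np.ndarray:
    """Upper-triangular change-of-basis matrix N_K.

    Column ``k`` holds the monomial coefficients of the degree-k (F)SVLF, so a
    row vector of fractional monomials ``[1, r**alpha, ..., r**(K alpha)]``
    times ``N_K`` reproduces the row vector of FSVLFs.
    """
    n = params.K + 1
    N = np.zeros((n, n))
    for k in range(n):
        N[: k + 1, k] = explicit_coefficients(k)
    return N


def fsvlf_roots(k: int, alpha: float = 1.0) -> np.ndarray:
    """The ``k`` roots of the degree-k FSVLF, sorted ascending, all in (0, 1).

    The SVLF roots are ``1/2 + cos((2p-1) pi / (2k)) / 2``; the fractional
    family's roots are their ``1/alpha`` powers.  The constant degree-0
    function has no roots and is rejected.
    """
    if k < 1:
        raise ValueError(f"roots are defined for degree k >= 1, got {k}")
    if alpha <= 0:
        raise ValueError(f"alpha must be positive, got {alpha}")
    p = np.arange(1, k + 1)
    s = 2.0 * np.cos((2 * p - 1) * np.pi / (2 * k))
    roots = (0.5 + s / 4.0) ** (1.0 / alpha)
    return np.sort(roots)


def _quadrature_beta(g: Callable, params: BasisParams, n: int) -> np.ndarray:
    # Substitute r**alpha = (1 + cos s)/2: the weighted integral collapses to
    # (2/(pi eta_k)) * int_0^pi cos(k s) g(r(s)) ds, free of endpoint
    # singularities; the midpoint rule in s is the Gauss-Chebyshev rule.
    s = (np.arange(n) + 0.5) * np.pi / n
    x = 0.5 * (1.0 + np.cos(s))
    r = x ** (1.0 / params.alpha)
    gv = np.asarray([g(float(ri)) for ri in r], dtype=float)
    ks = np.outer(np.arange(params.K + 1), s)
    eta = np.where(np.arange(params.K + 1) == 0, 4.0, 2.0)
    return (2.0 / (np.pi * eta)) * (np.cos(ks) @ gv) * (np.pi / n)


def project(
    g: Callable,
    params: BasisParams,
    tol: float = 1e-12,
    n_start: int = 64,
    n_max: int = 4096,
) -> ProjectionResult:
    """Weighted orthogonal projection of ``g`` onto the first K+1 FSVLFs.

    Computes ``beta_k = alpha/(pi eta_k) * int_0^1 V^alpha_k(r) g(r) w_alpha(r) dr``
    with weight ``w_alpha(r) = r**(alpha-1) / sqrt(r**alpha - r**(2 alpha))``.
    The cosine substitution removes the endpoint singularity of the weight;
    node counts are doubled (``n_start`` up to ``n_max``) until two successive
    coefficient vectors agree to ``tol``.

    Raises ``RuntimeError`` if node doubling never reaches ``tol``.
    """
    n = n_start
    beta = _quadrature_beta(g, params, n)
    while n < n_max:
        n *= 2
        beta_new = _quadrature_beta(g, params, n)
        err = np.max(np.abs(beta_new - beta))
        beta = beta_new
        if err < tol:
            break
    else:
        raise RuntimeError(
            f"projection quadrature did not converge to {tol:g} "
            f"within {n_max} nodes (last change {err:.3g})"
        )
    eta = np.where(np.arange(params.K + 1) == 0, 4.0, 2.0)
    return ProjectionResult(beta=beta, eta=eta, quadrature_nodes=n)


def theoretical_bounds(M_inf: float, K: int) -> BoundReport:
    """Closed-form expansion-coefficient and truncation-error bounds.

    ``M_inf`` is the sup of |g''| on [0, 1]; the bounds are stated for the
    alpha = 1 family.  ``coeff_bounds[k]`` is filled for k >= 2 (NaN below,
    where the bound does not apply).
    """
    if M_inf < 0:
        raise ValueError("M_inf must be nonnegative")
    if K < 1:
        raise ValueError("K must be >= 1")
    k = np.arange(K + 1, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        coeff = 4.0 * M_inf / (np.pi * k**4)
    coeff[:2] = np.nan
    return BoundReport(
        M_inf=M_inf,
        K=K,
        coeff_bounds=coeff,
        l2_tail_bound=math.sqrt(8.0 / (7.0 * math.pi)) * M_inf * K ** (-3.5),
        sup_tail_bound=8.0 * M_inf / (3.0 * math.pi) * K ** (-3.0),
        consecutive_bound=2.0 * math.sqrt(2.0) * M_inf / math.sqrt(math.pi) * K ** (-4.0),
    )
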