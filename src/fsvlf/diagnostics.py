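"""Residual error functions, error norms, convergence orders, comparators.

No closed-form solution of the bioheat BVP exists, so accuracy is measured by
the residual error function (REF): the absolute value of the original
nonlinear equation evaluated at the computed approximation.  The grid maximum
E_inf of the REF serves as the accuracy surrogate; the numerical convergence
order between truncations K and 2K is the log2 ratio of their E_inf values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import mpmath as mp
import numpy as np

from .basis import BasisParams
from .caputo import caputo_power, power_rule
from .solver import ModelSpec, SpectralSolution, evaluate, to_monomial
from . import solver as _solver

__all__ = [
    "ResidualReport",
    "ConvergenceTable",
    "residual",
    "max_residual",
    "convergence_order",
    "compare_to_reference",
    "manufactured_source",
]


@dataclass
class ResidualReport:
    """Pointwise REF magnitudes on a grid with their maximum E_inf."""

    grid: np.ndarray
    ref_values: np.ndarray
    e_inf: float
    K: int
    model: ModelSpec
    basis: BasisParams


@dataclass
class ConvergenceTable:
    """Rows (K, E_inf, ord) of a truncation sweep.

    ``ord`` between consecutive entries K and 2K is defined only where both
    error norms are positive; the first row's order is NaN.
    """

    K_values: Sequence[int]
    e_inf_values: Sequence[float]
    orders: Sequence[float]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"K": self.K_values, "E_inf": self.e_inf_values, "ord": self.orders})


def _fractional_derivative_terms(sol: SpectralSolution, q: float):
    """(coeff, exponent) arrays of D^q applied to the monomial form of sol."""
    coeff, expo, div = power_rule(sol.basis, q)
    if div.any():
        raise ValueError(
            f"order-{q} derivative of basis exponents {sol.basis.exponents[div]} "
            "is divergent; residual undefined"
        )
    mono = to_monomial(sol)
    return mono * coeff, expo


def residual(sol: SpectralSolution, model: ModelSpec, r: float) -> float:
    """REF at a single point r > 0 (r = 0 is defined as 0 by convention).

    |D^gamma h(r) + (A/r) D^sigma h(r) + lam exp(-m h(r)) - f(r)|, with both
    fractional derivatives applied term by term to the monomial form.
    """
    if r == 0.0:
        return 0.0
    if not 0.0 < r <= 1.0:
        raise ValueError(f"r must lie in (0, 1], got {r}")
    if sol.B_mp is not None:
        return _residual_mp(sol, model, np.array([r]))[0]
    cg, eg = _fractional_derivative_terms(sol, model.gamma)
    cs, es = _fractional_derivative_terms(sol, model.sigma)
    h = evaluate(sol, r)
    val = (cg @ r**eg) + (model.A / r) * (cs @ r**es) + model.lam * math.exp(-model.m * h)
    return abs(val - model.f(r))


def max_residual(sol: SpectralSolution, model: ModelSpec, n_grid: int = 2001) -> ResidualReport:
    """REF on a uniform grid over (0, 1] and its maximum E_inf.

    The grid is ``linspace(0, 1, n_grid)``; the REF at the excluded singular
    endpoint r = 0 is reported as 0 by convention.
    """
    if n_grid < 2:
        raise ValueError("n_grid must be >= 2")
    grid = np.linspace(0.0, 1.0, n_grid)
    interior = grid[1:]
    if sol.B_mp is not None:
        refs_i = _residual_mp(sol, model, interior)
    else:
        cg, eg = _fractional_derivative_terms(sol, model.gamma)
        cs, es = _fractional_derivative_terms(sol, model.sigma)
        h = evaluate(sol, interior)
        vals = (
            interior[:, None] ** eg @ cg
            + (model.A / interior) * (interior[:, None] ** es @ cs)
            + model.lam * np.exp(-model.m * h)
        )
        if model.source is not None:
            vals = vals - np.array([model.f(float(x)) for x in interior])
        refs_i = np.abs(vals)
    refs = np.concatenate([[0.0], refs_i])
    return ResidualReport(
        grid=grid,
        ref_values=refs,
        e_inf=float(np.max(refs)),
        K=sol.basis.K,
        model=model,
        basis=sol.basis,
    )


def _residual_mp(sol: SpectralSolution, model: ModelSpec, pts: np.ndarray) -> np.ndarray:
    """Extended-precision REF evaluation from the mpmath coefficient vector."""
    basis = sol.basis
    K = basis.K
    with mp.workdps(50):
        N = _solver._mp_basis_matrix(K)
        B = mp.matrix(sol.B_mp)
        mono = N * B
        alpha = mp.mpf(basis.alpha)
        expo = [alpha * ell for ell in range(K + 1)]
        cg = [_solver._mp_caputo_coeff(float(e), float(model.gamma)) for e in expo]
        cs = [_solver._mp_caputo_coeff(float(e), float(model.sigma)) for e in expo]
        lam, m, A = mp.mpf(model.lam), mp.mpf(model.m), mp.mpf(model.A)
        out = []
        for x in pts:
            r = mp.mpf(float(x))
            h = mp.fsum(mono[l] * r ** expo[l] for l in range(K + 1))
            dg = mp.fsum(
                mono[l] * cg[l] * r ** (expo[l] - mp.mpf(float(model.gamma)))
                for l in range(K + 1) if cg[l] != 0
            )
            ds = mp.fsum(
                mono[l] * cs[l] * r ** (expo[l] - mp.mpf(float(model.sigma)))
                for l in range(K + 1) if cs[l] != 0
            )
            val = dg + (A / r) * ds + lam * mp.e ** (-m * h) - mp.mpf(model.f(float(r)))
            out.append(float(abs(val)))
    return np.array(out)


def convergence_order(e_K: float, e_2K: float) -> float:
    """Numerical order of convergence (ln e_K - ln e_2K) / ln 2."""
    if e_K <= 0 or e_2K <= 0:
        raise ValueError("error norms must be positive")
    return (math.log(e_K) - math.log(e_2K)) / math.log(2.0)


def convergence_sweep(
    model: ModelSpec,
    K_values: Sequence[int],
    alpha: float = 1.0,
    n_grid: int = 2001,
    precision: str = "double",
) -> ConvergenceTable:
    """E_inf and numerical orders over a truncation sweep (typically K, 2K, 4K...)."""
    from .solver import SolverConfig, solve_qlm

    e_values = []
    for K in K_values:
        cfg = SolverConfig(basis=BasisParams(K=K, alpha=alpha), precision=precision)
        sol = solve_qlm(model, cfg)
        e_values.append(max_residual(sol, model, n_grid=n_grid).e_inf)
    orders = [float("nan")]
    for prev, cur in zip(e_values, e_values[1:]):
        orders.append(convergence_order(prev, cur) if prev > 0 and cur > 0 else float("nan"))
    return ConvergenceTable(K_values=list(K_values), e_inf_values=e_values, orders=orders)


def compare_to_reference(
    sol: SpectralSolution,
    ref_exponents: Sequence[float],
    ref_coeffs: Sequence[float],
    grid,
) -> np.ndarray:
    """Pointwise |h(r) - u_ref(r)| against a comparator polynomial.

    The reference is supplied as paired exponent/coefficient sequences (e.g. a
    printed least-squares polynomial); mismatched lengths are rejected.
    """
    ref_exponents = np.asarray(ref_exponents, dtype=float)
    ref_coeffs = np.asarray(ref_coeffs, dtype=float)
    if ref_exponents.shape != ref_coeffs.shape:
        raise ValueError("reference exponents and coefficients must pair up one-to-one")
    grid = np.atleast_1d(np.asarray(grid, dtype=float))
    ref_vals = grid[:, None] ** ref_exponents @ ref_coeffs
    return np.abs(evaluate(sol, grid) - ref_vals)


def manufactured_source(
    exponents: Sequence[float],
    coeffs: Sequence[float],
    model: ModelSpec,
):
    """Source term making a prescribed fractional polynomial the exact solution.

    For H*(r) = sum_j c_j r**(w_j), returns ``(f, Bi_star)`` where
    f(r) = D^gamma H* + (A/r) D^sigma H* + lam exp(-m H*), so H* solves the
    source-extended equation, and ``Bi_star = H*'(1) / (1 - H*(1))`` is the
    Biot number consistent with the Robin condition (None when H*(1) = 1 and
    any Bi works iff H*'(1) = 0).  Every exponent must be admissible for both
    derivative orders.
    """
    exponents = [float(w) for w in exponents]
    coeffs = [float(c) for c in coeffs]
    if len(exponents) != len(coeffs):
        raise ValueError("exponents and coefficients must pair up one-to-one")
    terms = {}
    for q in (model.gamma, model.sigma):
        ders = [caputo_power(w, q) for w in exponents]
        if any(d.divergent_flag for d in ders):
            bad = [w for w, d in zip(exponents, ders) if d.divergent_flag]
            raise ValueError(f"exponents {bad} inadmissible for order-{q} differentiation")
        terms[q] = ders

    def H_star(r):
        return sum(c * r**w for c, w in zip(coeffs, exponents))

    def f(r):
        dg = sum(c * d.coefficient * r**d.exponent
                 for c, d in zip(coeffs, terms[model.gamma]) if d.coefficient != 0.0)
        ds = sum(c * d.coefficient * r**d.exponent
                 for c, d in zip(coeffs, terms[model.sigma]) if d.coefficient != 0.0)
        return dg + (model.A / r) * ds + model.lam * math.exp(-model.m * H_star(r))

    h1 = H_star(1.0)
    dh1 = sum(c * w for c, w in zip(coeffs, exponents))
    Bi_star = None if h1 == 1.0 else dh1 / (1.0 - h1)
    return f, Bi_star
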