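"""Liouville-Caputo derivatives of power functions.

The collocation scheme only ever differentiates fractional monomials
``r**w``.  For the Liouville-Caputo operator of order ``q > 0`` the power rule
reads::

    D^q r**w = 0                                   w integer, w < ceil(q)
    D^q r**w = G(w+1)/G(w+1-q) * r**(w-q)          w integer, w >= ceil(q)
                                                   or w non-integer, w > floor(q)

with ``G`` the gamma function; constants are annihilated.  Non-integer powers
``w <= floor(q)`` fall outside the rule's domain of validity (the defining
integral diverges); they are flagged, not raised, so row assembly over a basis
can proceed and the caller can decide.  The gamma ratio is evaluated as
``G(w+1) * (1/G(w+1-q))`` through the reciprocal gamma, so poles of the
denominator yield a zero coefficient instead of an overflow.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln, rgamma

from .basis import BasisParams

__all__ = ["PowerDerivative", "caputo_power", "power_rule", "derivative_row"]

_INT_TOL = 1e-12


def _is_nonneg_integer(w: float) -> bool:
    return abs(w - round(w)) < _INT_TOL and round(w) >= 0


@dataclass(frozen=True)
class PowerDerivative:
    """Result of differentiating ``r**w``: ``coefficient * r**exponent``.

    ``divergent_flag`` marks the classically ill-defined region (non-integer
    ``w <= floor(q)``) where the returned zero coefficient is a convention,
    not a value of the operator.
    """

    coefficient: float
    exponent: float
    divergent_flag: bool = False


def caputo_power(w: float, q: float) -> PowerDerivative:
    """Liouville-Caputo derivative of order ``q`` of the power ``r**w``.

    Integer orders reduce to the classical derivative through the same
    formula.  See the module docstring for the branch structure.
    """
    if w < 0:
        raise ValueError(f"power w must be nonnegative, got {w}")
    if q <= 0:
        raise ValueError(f"order q must be positive, got {q}")
    if _is_nonneg_integer(w):
        if round(w) < math_ceil(q):
            return PowerDerivative(0.0, 0.0)
        return _gamma_ratio_branch(w, q)
    if w > np.floor(q):
        return _gamma_ratio_branch(w, q)
    # Non-integer w <= floor(q): outside the power rule's validity.
    return PowerDerivative(0.0, 0.0, divergent_flag=True)


def math_ceil(q: float) -> int:
    # ceil that treats q within _INT_TOL of an integer as that integer,
    # so e.g. ceil(2.0) = 2 even after float round-trips.
    if abs(q - round(q)) < _INT_TOL:
        return int(round(q))
    return int(np.ceil(q))


def _gamma_ratio_branch(w: float, q: float) -> PowerDerivative:
    # G(w+1)/G(w+1-q) via log-gamma (sign-safe: w+1 > 0) times the reciprocal
    # gamma of the denominator, which vanishes at its poles.
    a = w + 1.0
    b = w + 1.0 - q
    rg = float(rgamma(b))
    if rg == 0.0:
        return PowerDerivative(0.0, w - q)
    if b > 0:
        coeff = float(np.exp(gammaln(a) - gammaln(b)))
    else:
        coeff = float(np.exp(gammaln(a))) * rg
    return PowerDerivative(coeff, w - q)


def power_rule(params: BasisParams, q: float):
    """Vectors (coefficients, exponents, divergent flags) for the basis powers.

    Entry ``l`` differentiates ``r**(l*alpha)`` to order ``q``.  Computing the
    gamma ratios once per order keeps row evaluation on a grid O(K) per point.
    """
    ders = [caputo_power(float(w), q) for w in params.exponents]
    coeff = np.array([d.coefficient for d in ders])
    expo = np.array([d.exponent for d in ders])
    div = np.array([d.divergent_flag for d in ders])
    return coeff, expo, div


def derivative_row(r: float, params: BasisParams, q: float) -> np.ndarray:
    """Row vector of order-q LC derivatives of the fractional monomials at ``r``.

    Entry ``l`` is ``D^q r**(l*alpha)`` evaluated at ``r``.  ``q = 1`` gives
    the classical first-derivative row used by the boundary conditions.  At
    ``r = 0`` an entry with negative exponent and nonzero coefficient is
    singular and raises; divergent-flagged entries contribute zero with a
    warning.
    """
    if not 0.0 <= r <= 1.0:
        raise ValueError(f"r must lie in [0, 1], got {r}")
    coeff, expo, div = power_rule(params, q)
    if div.any():
        warnings.warn(
            f"order-{q} derivative of exponents {params.exponents[div]} is "
            "outside the Caputo power rule's validity; entries set to 0",
            RuntimeWarning,
            stacklevel=2,
        )
    row = np.zeros(params.K + 1)
    nz = coeff != 0.0
    if r == 0.0:
        if np.any(nz & (expo < -_INT_TOL)):
            raise ValueError(
                "singular derivative value at r = 0 (negative exponent with "
                "nonzero coefficient)"
            )
        zero_exp = nz & (np.abs(expo) <= _INT_TOL)
        row[zero_exp] = coeff[zero_exp]
        return row
    row[nz] = coeff[nz] * r ** expo[nz]
    return row
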