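import numpy as np
import pytest

from fsvlf import BasisParams, ModelSpec, SolverConfig, solve_qlm


@pytest.fixture(scope="session")
def head_model():
    """Integer-order bioheat benchmark: gamma=2, sigma=1, A=2, lam=m=Bi=1."""
    return ModelSpec()


@pytest.fixture(scope="session")
def fractional_model():
    """Fractional benchmark: gamma=1.7, sigma=0.7, A=2, lam=m=Bi=1."""
    return ModelSpec(gamma=1.7, sigma=0.7)


@pytest.fixture(scope="session")
def integer_solution_K6(head_model):
    return solve_qlm(head_model, SolverConfig(basis=BasisParams(K=6)))


@pytest.fixture(scope="session")
def integer_solution_K10(head_model):
    return solve_qlm(head_model, SolverConfig(basis=BasisParams(K=10)))


@pytest.fixture(scope="session")
def fractional_solution_K6(fractional_model):
    return solve_qlm(fractional_model, SolverConfig(basis=BasisParams(K=6, alpha=1.7)))


def assert_sig_digits(value, reference, digits):
    """Agreement to ``digits`` significant digits of the reference value."""
    import math

    thresh = 0.5 * 10 ** (math.floor(math.log10(abs(reference))) + 1 - digits)
    assert abs(value - reference) < thresh, (
        f"{value!r} differs from {reference!r} by {abs(value - reference):.3e} "
        f"(>{thresh:.1e}, {digits} significant digits)"
    )
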