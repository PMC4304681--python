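import numpy as np
import pytest

from gmma import fit_global, make_fixture_suite
from gmma.equilibria import Component, InteractionModel, Species


@pytest.fixture(scope="session")
def suite():
    """The bundled two-site demo suite (11 data sets, 4 techniques)."""
    return make_fixture_suite(seed=1)


@pytest.fixture(scope="session")
def suite_fit(suite):
    """Marquardt-Levenberg global fit of the demo suite."""
    return fit_global(
        suite.experiments, suite.model, suite.start_parameters,
        method="marquardt-levenberg",
    )


@pytest.fixture
def one_to_one():
    """Minimal 1:1 model A + B <-> AB with Kd = 1 uM."""
    return InteractionModel(
        components=[Component("A", s=3.0), Component("B", s=4.0)],
        species=[Species("AB", {"A": 1, "B": 1}, log10beta=6.0, dH=-10.0, s=6.0)],
    )


def closed_form_ab(a_tot: float, b_tot: float, kd: float) -> float:
    """Quadratic closed form for the 1:1 complex concentration (stable
    rationalized root, exact algebraic equivalent of
    (s - sqrt(s^2 - 4ab))/2 with s = A + B + Kd)."""
    s = a_tot + b_tot + kd
    return 2.0 * a_tot * b_tot / (s + np.sqrt(s * s - 4.0 * a_tot * b_tot))


def grid_oracle_1to1(a_tot, b_tot, k, n=20001):
    """Dense 1-D grid search minimizing the A mass-balance residual.

    Free B is eliminated through the B balance, so the residual is a
    function of free A alone; returns the grid's best free A.
    """
    fa = np.logspace(np.log10(a_tot) - 9, np.log10(a_tot), n)
    fb = b_tot / (1.0 + k * fa)
    resid = np.abs(fa + k * fa * fb - a_tot)
    return fa[np.argmin(resid)]


def grid_oracle_2to1(a_tot, b_tot, beta1, beta2, n=400):
    """Dense 2-D grid search minimizing the worst relative mass-balance
    error for A + B <-> AB <-> ABB; returns (free_A, free_B, spacing)."""
    fa = np.logspace(np.log10(a_tot) - 8, np.log10(a_tot), n)
    fb = np.logspace(np.log10(b_tot) - 8, np.log10(b_tot), n)
    FA, FB = np.meshgrid(fa, fb, indexing="ij")
    ab = beta1 * FA * FB
    abb = beta2 * FA * FB**2
    err_a = np.abs(FA + ab + abb - a_tot) / a_tot
    err_b = np.abs(FB + ab + 2 * abb - b_tot) / b_tot
    err = np.maximum(err_a, err_b)
    i, j = np.unravel_index(np.argmin(err), err.shape)
    spacing = np.log(fa[1] / fa[0])
    return fa[i], fb[j], spacing
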