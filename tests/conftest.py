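"""Shared fixtures: seeded generators and closed-form benchmark oracles."""

import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20240617)


def random_grassmann_points(rng, N, n, m, p):
    """Random Grassmann points from Gaussian trajectory matrices."""
    from trajgsa.grassmann import project_to_grassmann

    return [
        project_to_grassmann(rng.standard_normal((n, m)), p) for _ in range(N)
    ]


@pytest.fixture
def grassmann_ensemble(rng):
    return random_grassmann_points(rng, N=30, n=12, m=9, p=3)


def ishigami(X, a=7.0, b=0.1):
    """Ishigami benchmark function on [-pi, pi]^3."""
    return (
        np.sin(X[:, 0])
        + a * np.sin(X[:, 1]) ** 2
        + b * X[:, 2] ** 4 * np.sin(X[:, 0])
    )


def ishigami_analytic_indices(a=7.0, b=0.1):
    """Closed-form Sobol' indices of the Ishigami function.

    Derived from the variance decomposition of
    sin(x1) + a sin^2(x2) + b x3^4 sin(x1) for independent U(-pi, pi)
    inputs: V1 = (1 + b pi^4/5)^2 / 2, V2 = a^2/8, V13 = 8 b^2 pi^8 / 225,
    all other partial variances zero.
    """
    V1 = 0.5 * (1.0 + b * np.pi**4 / 5.0) ** 2
    V2 = a**2 / 8.0
    V13 = 8.0 * b**2 * np.pi**8 / 225.0
    V = V1 + V2 + V13
    S = np.array([V1 / V, V2 / V, 0.0])
    ST = np.array([(V1 + V13) / V, V2 / V, V13 / V])
    return S, ST


@pytest.fixture
def ishigami_problem():
    return ishigami, ishigami_analytic_indices
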