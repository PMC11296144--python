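"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately avoid the library's own code paths: centroids
by explicit double loops over spectrum bins, autocorrelation by explicit
circular lag sums, and the hereditary integral by dense trapezoid
quadrature.
"""

import numpy as np
import pytest

from skinmech.rheology import MaxwellBranches, PronyRelaxation, TestProtocol


@pytest.fixture
def single_cycle_protocol() -> TestProtocol:
    return TestProtocol(n_cycles=1)


@pytest.fixture
def one_branch_model() -> MaxwellBranches:
    # equilibrium spring 200 kPa, branch 400 kPa with tau = 3 s
    return MaxwellBranches(E0=200e3, branches=((400e3, 400e3 * 3.0),))


@pytest.fixture
def two_branch_model() -> MaxwellBranches:
    return MaxwellBranches(
        E0=200e3, branches=((400e3, 400e3 * 0.8), (300e3, 300e3 * 8.0)))


def brute_force_centroids(values: np.ndarray, u: np.ndarray,
                          v: np.ndarray) -> tuple[float, float]:
    """Exhaustive double-loop spectral centre of gravity.

    Weights are spectral magnitudes over the strictly positive frequency
    half-axis of the probed direction (all bins of the other direction),
    which excludes the DC bin by construction.
    """
    num_u = den_u = num_v = den_v = 0.0
    for i in range(values.shape[0]):
        for j in range(values.shape[1]):
            w = abs(values[i, j])
            if u[j] > 0:
                num_u += u[j] * w
                den_u += w
            if v[i] > 0:
                num_v += v[i] * w
                den_v += w
    return num_u / den_u, num_v / den_v


def brute_force_autocorrelation(img: np.ndarray) -> np.ndarray:
    """Normalized circular autocorrelation by explicit lag sums, centred."""
    f = img - img.mean()
    n, m = f.shape
    ac = np.empty((n, m))
    for dy in range(n):
        for dx in range(m):
            ac[dy, dx] = np.sum(f * np.roll(np.roll(f, -dy, axis=0), -dx, axis=1))
    ac /= ac[0, 0]
    return np.fft.fftshift(ac)


def quadrature_stress(p: PronyRelaxation, t: np.ndarray, strain_fn,
                      n_fine: int = 200_001) -> np.ndarray:
    """Dense-trapezoid hereditary integral for a differentiable strain
    history given as a callable (independent of the library's recursion)."""
    from skinmech.rheology import relaxation_modulus

    out = np.empty_like(t)
    for k, tk in enumerate(t):
        if tk == 0.0:
            out[k] = relaxation_modulus(p, 0.0) * strain_fn(0.0)
            continue
        zeta = np.linspace(0.0, tk, n_fine)
        dz = zeta[1] - zeta[0]
        rate = np.gradient(strain_fn(zeta), dz)
        integrand = relaxation_modulus(p, tk - zeta) * rate
        out[k] = relaxation_modulus(p, tk) * strain_fn(0.0) + np.trapezoid(integrand, zeta)
    return out
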