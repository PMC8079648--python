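import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from restormem import SyntheticSpec, SystemParams, make_bilateral_system

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def bilateral() -> SystemParams:
    """The seeded 15-region bilateral modular study system."""
    return make_bilateral_system(SyntheticSpec(seed=1))


@pytest.fixture()
def two_region_coupled() -> SystemParams:
    """H = (0, 0), J12 = 1: one attractor at (1, 1)."""
    return SystemParams(h=[0.0, 0.0], j=[[0.0, 1.0], [1.0, 0.0]])


def brute_energy(params: SystemParams, sigma) -> float:
    """Per-definition energy via explicit loops (test oracle)."""
    n = params.n_regions
    e = 0.0
    for i in range(n):
        e -= params.h[i] * sigma[i]
    for i in range(n):
        for j in range(i + 1, n):
            e -= params.j[i, j] * sigma[i] * sigma[j]
    return e


def brute_energies(params: SystemParams) -> list:
    n = params.n_regions
    out = []
    for k in range(2**n):
        sigma = [(k >> i) & 1 for i in range(n)]
        out.append(brute_energy(params, sigma))
    return out


def brute_minima(params: SystemParams) -> list:
    """0-based state indices that beat every 1-flip neighbor (oracle)."""
    n = params.n_regions
    e = brute_energies(params)
    return [
        k for k in range(2**n)
        if all(e[k] < e[k ^ (1 << i)] for i in range(n))
    ]


def brute_descend(params: SystemParams, k: int) -> int:
    """Steepest descent with lowest-flip-index tie-break (oracle)."""
    n = params.n_regions
    e = brute_energies(params)
    while True:
        best_i, best_e = None, e[k]
        for i in range(n):
            en = e[k ^ (1 << i)]
            if en < best_e:
                best_i, best_e = i, en
        if best_i is None:
            return k
        k = k ^ (1 << best_i)
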