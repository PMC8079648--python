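"""Exact state space of the pairwise maximum-entropy model.

For N regions the model assigns every binary activation pattern
(microstate) V_k an energy

    E(V_k) = - sum_i H_i sigma_i - sum_{i<j} J_ij sigma_i sigma_j

and a Boltzmann probability p(V_k) ∝ exp(-E(V_k)).  Everything here is
computed by full enumeration of the 2^N states, which is exact and fast
for the system sizes the model is used at (N up to ~20); there is no
Monte-Carlo fallback.

State labels are 1-based: label = 1 + sum_i sigma_i 2**i, so the
all-inactive pattern is state 1 and the all-active pattern state 2^N.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .params import State, SystemParams

__all__ = [
    "ENUMERATION_CAP",
    "StateTable",
    "state_matrix",
    "energy",
    "energies",
    "state_table",
    "expectations",
]

#: Largest N for which full 2^N enumeration is attempted by default.
ENUMERATION_CAP = 20


@lru_cache(maxsize=8)
def state_matrix(n_regions: int) -> np.ndarray:
    """(2^N, N) float matrix; row k holds the bits of state label k+1."""
    labels0 = np.arange(2**n_regions, dtype=np.int64)
    bits = (labels0[:, None] >> np.arange(n_regions)) & 1
    out = bits.astype(float)
    out.setflags(write=False)
    return out


def _check_cap(n: int, cap: int) -> None:
    if n > cap:
        raise ValueError(
            f"N={n} exceeds the exact-enumeration cap ({cap}); "
            "raise `cap` explicitly if you really want 2^N states"
        )


@dataclass(frozen=True)
class StateTable:
    """Energies and Boltzmann probabilities of all 2^N states.

    Row k corresponds to state label k+1.
    """

    energies: np.ndarray
    probabilities: np.ndarray

    @property
    def n_states(self) -> int:
        return self.energies.size


def energy(params: SystemParams, state: State | np.ndarray) -> float:
    """Energy of a single state: -Σ_i H_i σ_i - Σ_{i<j} J_ij σ_i σ_j."""
    sig = np.asarray(state.sigma if isinstance(state, State) else state,
                     dtype=float).reshape(-1)
    n = params.n_regions
    if sig.size != n:
        raise ValueError(
            f"state has {sig.size} regions but params has {n}"
        )
    return float(-(params.h @ sig) - 0.5 * sig @ params.j @ sig)


def energies(params: SystemParams, cap: int = ENUMERATION_CAP) -> np.ndarray:
    """Energies of all 2^N states, ordered by label."""
    n = params.n_regions
    _check_cap(n, cap)
    s = state_matrix(n)
    # J has zero diagonal, so the quadratic form double-counts each pair.
    return -(s @ params.h) - 0.5 * np.einsum("ki,ki->k", s @ params.j, s)


@lru_cache(maxsize=128)
def _state_table_cached(params: SystemParams, cap: int) -> StateTable:
    e = energies(params, cap=cap)
    loga = -e
    loga -= loga.max()
    p = np.exp(loga)
    p /= p.sum()
    e.setflags(write=False)
    p.setflags(write=False)
    return StateTable(energies=e, probabilities=p)


def state_table(params: SystemParams, cap: int = ENUMERATION_CAP) -> StateTable:
    """Exact Boltzmann distribution over all 2^N states.

    Normalization subtracts the maximum of -E before exponentiating, so
    large |H|, |J| do not overflow.  Tables are memoized on the
    parameter set (the iterative dynamics revisit systems constantly).
    """
    return _state_table_cached(params, cap)


@lru_cache(maxsize=128)
def expectations(
    params: SystemParams, cap: int = ENUMERATION_CAP
) -> tuple[np.ndarray, np.ndarray]:
    """Model moments ⟨σ_i⟩ and ⟨σ_i σ_j⟩ under the exact distribution.

    Returns
    -------
    mean_activation : (N,) array
    mean_coactivation : (N, N) array
        Symmetric; the diagonal equals ``mean_activation`` because
        σ_i² = σ_i for binary states.
    """
    table = state_table(params, cap=cap)
    s = state_matrix(params.n_regions)
    p = table.probabilities
    mean_act = p @ s
    mean_coact = (s * p[:, None]).T @ s
    # exact symmetry despite floating-point matmul
    mean_coact = 0.5 * (mean_coact + mean_coact.T)
    np.fill_diagonal(mean_coact, mean_act)
    mean_act.setflags(write=False)
    mean_coact.setflags(write=False)
    return mean_act, mean_coact
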