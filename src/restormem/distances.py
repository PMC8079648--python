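"""Functional and parametric distances between systems.

Two systems can be compared in *dynamics space* — a partial
Kullback–Leibler divergence between their microstate distributions,
restricted to the basin states of the reference system's major
attractors — or in *parameter space*, a root-mean-square deviation of
their H/J vectors.  The two deliberately disagree under degeneracy:
different parameter sets can generate nearly identical dynamics.

The partial KL sum uses the full normalized distributions of both
systems without renormalizing over the support set; restricted sums can
therefore be negative, and only the full-support case is a true KL
divergence (non-negative by Gibbs' inequality).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable

import numpy as np

from .landscape import assign_basins, major_attractors
from .mem import state_table
from .params import SystemParams

__all__ = [
    "DistanceReport",
    "partial_kl",
    "default_support",
    "rmsd",
    "recovery_capacity",
]


def _check_same_n(a: SystemParams, b: SystemParams) -> int:
    if a.n_regions != b.n_regions:
        raise ValueError(
            f"systems differ in size: {a.n_regions} vs {b.n_regions}"
        )
    return a.n_regions


def partial_kl(
    ref: SystemParams,
    other: SystemParams,
    support: Iterable[int] | None = None,
) -> float:
    """Partial KL divergence  Σ_{k∈R} p(V_k|ref) ln[p(V_k|ref)/p(V_k|other)].

    ``ref`` plays the asymmetric reference role (its probabilities weight
    the log-ratios).  ``support`` is a set of 1-based state labels R;
    ``None`` means all 2^N states (full KL).  Probabilities are taken
    from the full normalized distributions of both systems — they are
    not renormalized over R.
    """
    n = _check_same_n(ref, other)
    p = state_table(ref).probabilities
    q = state_table(other).probabilities
    if support is None:
        idx = slice(None)
    else:
        idx = support_index(support, n)
    pr, qr = p[idx], q[idx]
    return float(np.sum(pr * (np.log(pr) - np.log(qr))))


@lru_cache(maxsize=32)
def _support_index_cached(support: frozenset, n: int) -> np.ndarray:
    labels = np.asarray(sorted(support), dtype=np.int64)
    if labels.size == 0:
        raise ValueError("support is empty")
    if labels.min() < 1 or labels.max() > 2**n:
        raise ValueError("support labels out of range")
    idx = labels - 1
    idx.setflags(write=False)
    return idx


def support_index(support: Iterable[int], n: int) -> np.ndarray:
    """0-based sorted index array for a support set of 1-based labels."""
    if not isinstance(support, frozenset):
        support = frozenset(int(s) for s in support)
    return _support_index_cached(support, n)


@lru_cache(maxsize=64)
def default_support(ref: SystemParams, k_major: int = 5) -> frozenset[int]:
    """State labels in the basins of ``ref``'s top-``k_major`` attractors.

    This is the support set R over which partial KL divergences are
    taken.  Which system's basins define R is a modelling choice (the
    reference system's is used here); recompute whenever the reference
    changes.
    """
    ls = assign_basins(ref)
    majors = major_attractors(ls, k=k_major)
    labels: set[int] = set()
    for st in majors:
        labels.update(int(x) for x in ls.basin_labels(st.label))
    return frozenset(labels)


def rmsd(
    a: SystemParams,
    b: SystemParams,
    which: str = "all",
    norm: str = "rms",
) -> float:
    """Parameter-space deviation between two systems.

    ``which`` selects the coordinates: ``"J"`` uses the upper-triangle
    off-diagonal interactions only, ``"H"`` the sensitivities, ``"all"``
    both.  ``norm="rms"`` (default) is the root-mean-square difference,
    comparable across subsets of different size; ``norm="euclidean"``
    is the plain vector norm.
    """
    n = _check_same_n(a, b)
    iu = np.triu_indices(n, k=1)
    if which == "J":
        diff = (a.j - b.j)[iu]
    elif which == "H":
        diff = a.h - b.h
    elif which == "all":
        diff = np.concatenate([a.h - b.h, (a.j - b.j)[iu]])
    else:
        raise ValueError(f"which must be 'J', 'H' or 'all', got {which!r}")
    if norm == "rms":
        return float(np.sqrt(np.mean(diff**2)))
    if norm == "euclidean":
        return float(np.linalg.norm(diff))
    raise ValueError(f"norm must be 'rms' or 'euclidean', got {norm!r}")


def recovery_capacity(
    pre: SystemParams,
    treated: SystemParams,
    recovered: SystemParams,
    support: Iterable[int] | None = None,
) -> float:
    """ΔD = D(pre, treated) − D(pre, recovered).

    How much of the functional deviation caused by a treatment the
    self-restoration process undid; positive when recovery moved the
    dynamics back toward the pre-treatment system.
    """
    _check_same_n(pre, treated)
    _check_same_n(pre, recovered)
    support = None if support is None else frozenset(support)
    return partial_kl(pre, treated, support) - partial_kl(
        pre, recovered, support
    )


@dataclass(frozen=True)
class DistanceReport:
    """Bundle of the functional and parametric distances between two systems."""

    partial_kl: float
    rmsd_j: float
    rmsd_all: float
    support_labels: tuple[int, ...]
    reference_system: str = "target"

    @classmethod
    def compute(
        cls,
        ref: SystemParams,
        other: SystemParams,
        support: Iterable[int] | None = None,
        k_major: int = 5,
        reference_system: str = "target",
    ) -> "DistanceReport":
        if support is None:
            support = default_support(ref, k_major=k_major)
        support = tuple(sorted(set(int(s) for s in support)))
        return cls(
            partial_kl=partial_kl(ref, other, support),
            rmsd_j=rmsd(ref, other, which="J"),
            rmsd_all=rmsd(ref, other, which="all"),
            support_labels=support,
            reference_system=reference_system,
        )

    def to_json(self, path: str | None = None) -> dict:
        out = {
            "partial_kl": self.partial_kl,
            "rmsd_j": self.rmsd_j,
            "rmsd_all": self.rmsd_all,
            "n_support_states": len(self.support_labels),
            "support_labels": list(self.support_labels),
            "reference_system": self.reference_system,
        }
        if path is not None:
            with open(path, "w") as fh:
                json.dump(out, fh, indent=1)
        return out
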