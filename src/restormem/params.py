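"""System parameters for the pairwise maximum-entropy (Ising-type) model.

A system is a set ``A = {H_i, J_ij}``: per-region baseline sensitivities
``H`` and a symmetric pairwise-interaction matrix ``J`` with zero diagonal.
Both are dimensionless.  Parameter files come in two dialects:

* CSV matrix with ``H`` on the diagonal and ``J`` off-diagonal,
* JSON ``{"labels": [...], "H": [...], "J": [[...]]}``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["SystemParams", "State", "read_params", "write_params"]

_SYM_TOL = 1e-9


@dataclass(frozen=True)
class SystemParams:
    """One network system ``A = {H_i, J_ij}``.

    Parameters
    ----------
    h : (N,) array
        Baseline sensitivity of each region.
    j : (N, N) array
        Symmetric pairwise interactions, zero diagonal.
    region_labels : list of str, optional
        Region names; defaults to ``R0..R{N-1}``.
    """

    h: np.ndarray
    j: np.ndarray
    region_labels: tuple[str, ...] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        h = np.asarray(self.h, dtype=float).reshape(-1)
        j = np.asarray(self.j, dtype=float)
        n = h.size
        if n < 2:
            raise ValueError(f"need at least 2 regions, got {n}")
        if j.shape != (n, n):
            raise ValueError(
                f"J shape {j.shape} does not match {n} regions from H"
            )
        if not np.allclose(j, j.T, atol=_SYM_TOL, rtol=0.0):
            raise ValueError("J must be symmetric (|J - J.T| < 1e-9)")
        j = 0.5 * (j + j.T)
        np.fill_diagonal(j, 0.0)
        h.setflags(write=False)
        j.setflags(write=False)
        object.__setattr__(self, "h", h)
        object.__setattr__(self, "j", j)
        labels = self.region_labels
        if labels is None:
            labels = tuple(f"R{i}" for i in range(n))
        else:
            labels = tuple(str(x) for x in labels)
            if len(labels) != n:
                raise ValueError(
                    f"{len(labels)} labels for {n} regions"
                )
        object.__setattr__(self, "region_labels", labels)

    @property
    def n_regions(self) -> int:
        return self.h.size

    def replace(self, h: np.ndarray | None = None,
                j: np.ndarray | None = None) -> "SystemParams":
        """Return a copy with ``h`` and/or ``j`` substituted."""
        return SystemParams(
            h=self.h if h is None else h,
            j=self.j if j is None else j,
            region_labels=self.region_labels,
        )

    def copy_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """Writable copies of (h, j)."""
        return self.h.copy(), self.j.copy()

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SystemParams):
            return NotImplemented
        return (
            np.array_equal(self.h, other.h)
            and np.array_equal(self.j, other.j)
        )

    def __hash__(self) -> int:  # frozen dataclass wants one
        return hash((self.h.tobytes(), self.j.tobytes()))


@dataclass(frozen=True)
class State:
    """A binary activation pattern (microstate) over N regions.

    The integer label is ``1 + sum_i sigma_i 2**i`` so the all-inactive
    state has label 1 and the all-active state label ``2**N``.
    """

    sigma: tuple[int, ...]

    def __post_init__(self) -> None:
        sig = tuple(int(s) for s in self.sigma)
        if any(s not in (0, 1) for s in sig):
            raise ValueError("state entries must be 0 or 1")
        object.__setattr__(self, "sigma", sig)

    @property
    def label(self) -> int:
        return 1 + sum(s << i for i, s in enumerate(self.sigma))

    @classmethod
    def from_label(cls, label: int, n_regions: int) -> "State":
        if not 1 <= label <= 2**n_regions:
            raise ValueError(f"label {label} out of [1, {2**n_regions}]")
        v = label - 1
        return cls(tuple((v >> i) & 1 for i in range(n_regions)))


def read_params(path: str) -> SystemParams:
    """Read a parameter set from CSV (H diagonal, J off-diagonal) or JSON.

    A nearly-symmetric J (asymmetry above 1e-9) is symmetrized by
    averaging with a warning; grossly asymmetric input raises.
    """
    path = str(path)
    if path.endswith(".json"):
        with open(path) as fh:
            obj = json.load(fh)
        h = np.asarray(obj["H"], dtype=float)
        j = np.asarray(obj["J"], dtype=float)
        labels = obj.get("labels")
    else:
        df = pd.read_csv(path, index_col=0, float_precision="round_trip")
        mat = df.to_numpy(dtype=float)
        h = np.diag(mat).copy()
        j = mat.copy()
        np.fill_diagonal(j, 0.0)
        labels = list(df.columns)
    asym = np.abs(j - j.T).max()
    if asym > 1e-6:
        raise ValueError(f"J asymmetry {asym:.3g} too large to repair")
    if asym > _SYM_TOL:
        warnings.warn(
            f"J asymmetric by {asym:.3g}; symmetrizing by averaging",
            stacklevel=2,
        )
    j = 0.5 * (j + j.T)
    return SystemParams(h=h, j=j, region_labels=labels)


def write_params(params: SystemParams, path: str) -> None:
    """Write a parameter set in the dialect implied by the extension."""
    path = str(path)
    if path.endswith(".json"):
        obj = {
            "labels": list(params.region_labels),
            "H": params.h.tolist(),
            "J": params.j.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=1)
    else:
        mat = params.j.copy()
        np.fill_diagonal(mat, params.h)
        df = pd.DataFrame(
            mat, index=params.region_labels, columns=params.region_labels
        )
        df.to_csv(path)  # default repr formatting round-trips float64
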