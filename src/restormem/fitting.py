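"""Maximum-likelihood estimation of pairwise MEM parameters.

Fits {H_i, J_ij} to binarized multichannel activity by iterated
moment matching: parameters move by the difference between the log of
the empirical activation/coactivation moments and the log of the exact
model moments.  Because the pairwise MEM is an exponential family,
matching the first- and second-order moments is exactly maximum
likelihood, and the exact model moments come from full enumeration
(module `mem`), so the only approximation is the finite sample.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .mem import expectations, state_table
from .params import SystemParams

__all__ = [
    "BinaryRecording",
    "FitResult",
    "empirical_moments",
    "fit_mem",
    "binarize",
    "read_recording",
]


@dataclass(frozen=True)
class BinaryRecording:
    """T x N matrix of binarized activity (rows = time, cols = regions)."""

    data: np.ndarray
    region_labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        if data.ndim != 2 or data.shape[0] < 1:
            raise ValueError("recording must be a T x N matrix with T >= 1")
        if not np.isin(data, (0, 1)).all():
            raise ValueError("recording entries must be 0 or 1")
        data = data.astype(np.int8)
        data.setflags(write=False)
        object.__setattr__(self, "data", data)
        if self.region_labels is not None:
            labels = tuple(str(x) for x in self.region_labels)
            if len(labels) != data.shape[1]:
                raise ValueError("label count does not match columns")
            object.__setattr__(self, "region_labels", labels)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_regions(self) -> int:
        return self.data.shape[1]


@dataclass(frozen=True)
class FitResult:
    params: SystemParams
    log_likelihood_curve: np.ndarray
    converged: bool
    iterations: int


def empirical_moments(
    rec: BinaryRecording | np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Time-averaged <sigma_i> and <sigma_i sigma_j> of a recording."""
    if not isinstance(rec, BinaryRecording):
        rec = BinaryRecording(rec)
    x = rec.data.astype(float)
    mean_act = x.mean(axis=0)
    mean_coact = (x.T @ x) / x.shape[0]
    mean_coact = 0.5 * (mean_coact + mean_coact.T)
    np.fill_diagonal(mean_coact, mean_act)
    return mean_act, mean_coact


def _log_likelihood(
    params: SystemParams, mean_act: np.ndarray, mean_coact: np.ndarray
) -> float:
    """Per-sample expected log-likelihood of data with the given moments."""
    tbl = state_table(params)
    logz = float(
        np.log(np.sum(np.exp(-tbl.energies + tbl.energies.min())))
        - tbl.energies.min()
    )
    iu = np.triu_indices(params.n_regions, k=1)
    return float(
        params.h @ mean_act + params.j[iu] @ mean_coact[iu] - logz
    )


def fit_mem(
    rec: BinaryRecording | np.ndarray,
    lr: float = 0.2,
    tol: float = 1e-6,
    max_iters: int = 20_000,
    update: str = "log",
    moments: tuple[np.ndarray, np.ndarray] | None = None,
) -> FitResult:
    """Gradient-ascent fit of the pairwise MEM to a recording.

    Iterates  H_i += lr*(log m_i - log m_i(A))  and the J analog until
    the largest log-moment gap falls below ``tol``.  ``update="raw"``
    uses plain moment differences (the literal likelihood gradient)
    instead of log differences.  ``moments`` may supply precomputed
    (or exact population) moments directly, in which case ``rec`` is
    ignored; empirical moments at 0 or 1 are floored into (0, 1) at
    1/(2T) with a warning since their logs are otherwise undefined.
    """
    if moments is None:
        if not isinstance(rec, BinaryRecording):
            rec = BinaryRecording(rec)
        mean_act, mean_coact = empirical_moments(rec)
        floor = 1.0 / (2 * rec.n_samples)
        n = rec.n_regions
        labels = rec.region_labels
    else:
        mean_act, mean_coact = moments
        mean_act = np.asarray(mean_act, float)
        mean_coact = np.asarray(mean_coact, float)
        floor = 1e-12
        n = mean_act.size
        labels = None
    if ((mean_act <= 0) | (mean_act >= 1)).any() or (
        (mean_coact <= 0) | (mean_coact >= 1)
    ).any():
        warnings.warn(
            f"degenerate empirical moments floored into ({floor:.3g}, "
            f"{1 - floor:.3g})", stacklevel=2,
        )
    mean_act = np.clip(mean_act, floor, 1 - floor)
    mean_coact = np.clip(mean_coact, floor, 1 - floor)

    iu = np.triu_indices(n, k=1)
    h = np.zeros(n)
    j = np.zeros((n, n))
    ll_curve: list[float] = []
    halvings = 0
    params = SystemParams(h=h, j=j, region_labels=labels)
    ll_prev = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iters + 1):
        model_act, model_coact = expectations(params)
        model_act = np.clip(model_act, 1e-300, None)
        model_coact = np.clip(model_coact, 1e-300, None)
        if update == "log":
            gh = np.log(mean_act) - np.log(model_act)
            gj = np.log(mean_coact[iu]) - np.log(model_coact[iu])
        else:
            gh = mean_act - model_act
            gj = mean_coact[iu] - model_coact[iu]
        gap = max(
            np.abs(np.log(mean_act) - np.log(model_act)).max(),
            np.abs(np.log(mean_coact[iu]) - np.log(model_coact[iu])).max(),
        )
        ll = _log_likelihood(params, mean_act, mean_coact)
        ll_curve.append(ll)
        if gap < tol:
            converged = True
            break
        if ll < ll_prev - 1e-9:
            halvings += 1
            if halvings > 6:
                raise RuntimeError(
                    f"fit diverged: log-likelihood fell at iteration {it} "
                    f"even after 6 learning-rate halvings (lr={lr:.3g}, "
                    f"gap={gap:.3g})"
                )
            lr *= 0.5
        ll_prev = ll
        h = h + lr * gh
        j = j.copy()
        j[iu] += lr * gj
        j.T[iu] = j[iu]
        params = SystemParams(h=h, j=j, region_labels=labels)
    return FitResult(
        params=params,
        log_likelihood_curve=np.asarray(ll_curve),
        converged=converged,
        iterations=it,
    )


def binarize(
    signals: np.ndarray | pd.DataFrame,
    method: str = "median",
    threshold: float | np.ndarray | None = None,
) -> BinaryRecording:
    """Threshold continuous signals into a binary recording.

    Each region is binarized against its own ``median`` (default) or
    ``mean``, or against an explicit ``threshold`` (scalar or
    per-region).  The threshold convention is preprocessing, not part of
    the model; make it explicit in any analysis.
    """
    labels = None
    if isinstance(signals, pd.DataFrame):
        labels = tuple(signals.columns.astype(str))
        signals = signals.to_numpy(dtype=float)
    signals = np.asarray(signals, dtype=float)
    if threshold is None:
        if method == "median":
            threshold = np.median(signals, axis=0)
        elif method == "mean":
            threshold = signals.mean(axis=0)
        else:
            raise ValueError("method must be 'median' or 'mean'")
    return BinaryRecording(
        (signals > threshold).astype(np.int8), region_labels=labels
    )


def read_recording(path: str) -> BinaryRecording:
    """Read a binary recording CSV (header row = region labels)."""
    df = pd.read_csv(path)
    return BinaryRecording(
        df.to_numpy(), region_labels=tuple(df.columns.astype(str))
    )


def write_recording(rec: BinaryRecording, path: str) -> None:
    labels = rec.region_labels or tuple(
        f"R{i}" for i in range(rec.n_regions)
    )
    pd.DataFrame(rec.data, columns=list(labels)).to_csv(path, index=False)
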