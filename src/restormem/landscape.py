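"""Energy-landscape analysis of the exact MEM state space.

A *local minimum* (attractor, LM) is a state with strictly lower energy
than all of its N Hamming-distance-1 neighbors.  Every state is assigned
to a basin by discrete steepest descent: repeatedly flip the single
region that lowers energy the most, until a local minimum is reached.
The occupation-time ratio (OCR) of a minimum is the total Boltzmann
probability of its basin.

The descent rule is a choice: the definition of a basin only says states
are moved "along the energy gradient", which on the hypercube leaves the
visit order open.  Steepest descent with a deterministic tie-break
(lowest flipped-region index) is used because it is order-free and
reproducible; for generic real-valued parameters ties never occur.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np

from .mem import ENUMERATION_CAP, StateTable, state_table
from .params import State, SystemParams

__all__ = ["Landscape", "find_local_minima", "assign_basins",
           "major_attractors", "export_landscape"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Landscape:
    """Exhaustive landscape summary of one system.

    Attributes
    ----------
    minima : tuple of int
        Local-minimum state labels, sorted by descending OCR (ties by
        lower label).
    basin_of : (2^N,) int array
        ``basin_of[k]`` is the label of the minimum whose basin contains
        state label ``k+1``.
    ocr : dict
        Minimum label -> occupation-time ratio in [0, 1]; sums to 1.
    table : StateTable
        Energies and probabilities underlying the landscape.
    n_regions : int
    """

    minima: tuple[int, ...]
    basin_of: np.ndarray
    ocr: dict[int, float]
    table: StateTable
    n_regions: int

    def basin_labels(self, minimum_label: int) -> np.ndarray:
        """1-based labels of all states in the given minimum's basin."""
        return np.flatnonzero(self.basin_of == minimum_label) + 1

    def minimum_states(self) -> list[State]:
        return [State.from_label(m, self.n_regions) for m in self.minima]


def _neighbor_energies(e: np.ndarray, n: int) -> np.ndarray:
    """(2^N, N) energies of the single-flip neighbors of every state."""
    labels0 = np.arange(e.size, dtype=np.int64)
    nbr = labels0[:, None] ^ (np.int64(1) << np.arange(n, dtype=np.int64))
    return e[nbr], nbr


def find_local_minima(
    params: SystemParams, cap: int = ENUMERATION_CAP
) -> list[State]:
    """All states with strictly lower energy than every 1-flip neighbor.

    Returned sorted by label; may be empty (e.g. a flat landscape).
    """
    tbl = state_table(params, cap=cap)
    n = params.n_regions
    nbr_e, _ = _neighbor_energies(tbl.energies, n)
    is_min = (tbl.energies[:, None] < nbr_e).all(axis=1)
    return [State.from_label(k + 1, n) for k in np.flatnonzero(is_min)]


def assign_basins(params: SystemParams, cap: int = ENUMERATION_CAP) -> Landscape:
    """Assign every state to a local minimum by steepest descent.

    From each state, move to the 1-flip neighbor of minimal energy while
    that energy is strictly lower than the current one (ties between
    equal-energy best neighbors break to the lowest flipped-region
    index).  Assignment is propagated by pointer doubling, so the whole
    state space resolves in O(N·2^N log) work.

    Degenerate plateaus (a state that is not a strict minimum but has no
    strictly lower neighbor) are resolved by a guarded equal-energy walk;
    generic real parameters never produce them.
    """
    tbl = state_table(params, cap=cap)
    n = params.n_regions
    e = tbl.energies
    nbr_e, nbr = _neighbor_energies(e, n)

    best_flip = np.argmin(nbr_e, axis=1)  # lowest index wins ties
    rows = np.arange(e.size)
    best_e = nbr_e[rows, best_flip]
    succ = np.where(best_e < e, nbr[rows, best_flip], rows)

    is_min = succ == rows
    plateau = is_min & ~(e[:, None] < nbr_e).all(axis=1)
    if not np.any(is_min & ~plateau):
        raise ValueError("landscape has no strict local minimum")
    if plateau.any():
        succ = _resolve_plateaus(succ, plateau, e, nbr_e, nbr)

    # pointer doubling until every chain terminates at a fixed point
    for _ in range(2 * n + 2):
        nxt = succ[succ]
        if np.array_equal(nxt, succ):
            break
        succ = nxt
    else:  # pragma: no cover - descent shortens energy, cannot cycle
        raise RuntimeError("basin descent did not converge")

    basin_of = succ + 1  # to 1-based labels
    p = tbl.probabilities
    minima0 = np.flatnonzero((e[:, None] < nbr_e).all(axis=1))
    ocr_raw = {
        int(m + 1): float(p[succ == m].sum()) for m in minima0
    }
    order = sorted(ocr_raw, key=lambda lbl: (-ocr_raw[lbl], lbl))
    basin_of.setflags(write=False)
    return Landscape(
        minima=tuple(order),
        basin_of=basin_of,
        ocr={lbl: ocr_raw[lbl] for lbl in order},
        table=tbl,
        n_regions=n,
    )


def _resolve_plateaus(
    succ: np.ndarray,
    plateau: np.ndarray,
    e: np.ndarray,
    nbr_e: np.ndarray,
    nbr: np.ndarray,
) -> np.ndarray:
    """Equal-energy walk with a visited-set cycle guard for flat patches."""
    succ = succ.copy()
    strict_min = (e[:, None] < nbr_e).all(axis=1)
    for k in np.flatnonzero(plateau):
        visited = {int(k)}
        cur = int(k)
        while True:
            if strict_min[cur]:
                succ[k] = cur
                break
            cands = nbr[cur][nbr_e[cur] <= e[cur]]
            step = next((int(c) for c in np.sort(cands)
                         if int(c) not in visited), None)
            if step is None:
                # guard exhausted: lowest-label strict minimum reachable
                # by any non-increasing path; fall back to global search
                succ[k] = _lowest_reachable_min(int(k), e, nbr_e, nbr,
                                                strict_min)
                break
            visited.add(step)
            cur = step


    return succ


def _lowest_reachable_min(
    start: int, e: np.ndarray, nbr_e: np.ndarray, nbr: np.ndarray,
    strict_min: np.ndarray
) -> int:
    frontier = [start]
    seen = {start}
    found: list[int] = []
    while frontier:
        cur = frontier.pop()
        if strict_min[cur]:
            found.append(cur)
            continue
        for c in nbr[cur][nbr_e[cur] <= e[cur]]:
            c = int(c)
            if c not in seen:
                seen.add(c)
                frontier.append(c)
    if not found:  # pragma: no cover
        raise RuntimeError("no minimum reachable from plateau")
    return min(found)


def major_attractors(
    ls: Landscape,
    k: int | None = 5,
    ocr_threshold: float | None = None,
) -> list[State]:
    """Top minima by occupation-time ratio.

    With ``k`` (default 5), the k highest-OCR minima, ties broken by
    lower state label.  With ``ocr_threshold``, the smallest prefix of
    the OCR-sorted minima whose cumulative OCR reaches the threshold.
    """
    if ocr_threshold is not None:
        if not 0.0 < ocr_threshold <= 1.0:
            raise ValueError("ocr_threshold must be in (0, 1]")
        cum = 0.0
        chosen: list[int] = []
        for lbl in ls.minima:
            chosen.append(lbl)
            cum += ls.ocr[lbl]
            if cum >= ocr_threshold:
                break
        return [State.from_label(lbl, ls.n_regions) for lbl in chosen]
    if k is None or k < 1:
        raise ValueError("k must be >= 1")
    if k > len(ls.minima):
        logger.warning(
            "requested %d major attractors but only %d minima exist",
            k, len(ls.minima),
        )
    return [State.from_label(lbl, ls.n_regions) for lbl in ls.minima[:k]]


def export_landscape(ls: Landscape, path: str | None = None) -> dict:
    """JSON-ready landscape summary (written to ``path`` if given).

    OCRs are reported both as fractions and as percentages, and each
    minimum carries its binary activation pattern and basin size.
    """
    basin_sizes = {
        lbl: int((ls.basin_of == lbl).sum()) for lbl in ls.minima
    }
    out = {
        "n_regions": ls.n_regions,
        "n_minima": len(ls.minima),
        "minima": [
            {
                "label": lbl,
                "pattern": list(State.from_label(lbl, ls.n_regions).sigma),
                "energy": float(ls.table.energies[lbl - 1]),
                "ocr": ls.ocr[lbl],
                "ocr_percent": 100.0 * ls.ocr[lbl],
                "basin_size": basin_sizes[lbl],
            }
            for lbl in ls.minima
        ],
    }
    if path is not None:
        with open(path, "w") as fh:
            json.dump(out, fh, indent=1)
    return out


def plot_landscape(ls: Landscape, ax=None, top: int = 10):
    """Bubble chart of minima: x = state label, y = energy, size = OCR."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    labels = list(ls.minima[:top])
    es = [ls.table.energies[lbl - 1] for lbl in labels]
    sizes = [4000.0 * ls.ocr[lbl] for lbl in labels]
    ax.scatter(labels, es, s=sizes, alpha=0.6, edgecolor="k")
    for lbl, e in zip(labels, es):
        ax.annotate(f"{lbl}\n{100 * ls.ocr[lbl]:.1f}%", (lbl, e),
                    fontsize=7, ha="center")
    ax.set_xlabel("state label")
    ax.set_ylabel("energy")
    return ax
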