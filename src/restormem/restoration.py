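"""Self-restoration dynamics of a treated network.

After a treatment perturbs one coordinate of the system (a node's H or
an edge's J), the *neighbors* of the treated element — the coordinates
strongly coupled to it — readjust to pull the system's activation
statistics back toward those of the pre-treatment system.  The update is
the log-moment-matching rule also used for maximum-likelihood MEM
fitting:

    H_i  <- H_i  + a_g (log<s_i>_pre   - log<s_i>_current)
    J_ij <- J_ij + a_g (log<s_is_j>_pre - log<s_is_j>_current)

applied only on the neighbor coordinates, with three biological
constraints: a per-step cap tying each coordinate's change to its change
in the previous step, a box bound keeping every recovering parameter
within a fraction of its pre-treatment value, and (optionally) additive
Gaussian noise on each applied change for Monte-Carlo exploration of
restoration variability.

The dynamics recover *function*, not parameters: the functional distance
(partial KL divergence) to the pre-treatment system falls while the
parameter-space distance (RMSD of J) typically grows — degeneracy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .distances import partial_kl, rmsd
from .mem import expectations
from .params import SystemParams

__all__ = [
    "Target",
    "TreatmentSpec",
    "RecoveryConfig",
    "RecoveryTrace",
    "RecoveryDiverged",
    "apply_treatment",
    "neighbor_set",
    "recovery_step",
    "run_recovery",
    "stabilize",
]

# A parameter coordinate: ("H", i) or ("J", i, j) with i < j.
Coord = tuple

_LOG_FLOOR = 1e-12
_CAP_FLOOR = 1e-6


@dataclass(frozen=True)
class Target:
    """One treated element: a node's H or an edge's J, shifted by alpha."""

    kind: str  # "node" | "edge"
    index: int | tuple[int, int]
    alpha: float = 0.0

    def __post_init__(self) -> None:
        if self.kind == "node":
            object.__setattr__(self, "index", int(self.index))
        elif self.kind == "edge":
            i, j = self.index  # type: ignore[misc]
            i, j = int(i), int(j)
            if i == j:
                raise ValueError("edge target needs two distinct regions")
            object.__setattr__(self, "index", (min(i, j), max(i, j)))
        else:
            raise ValueError(f"kind must be 'node' or 'edge', got {self.kind!r}")

    def coord(self) -> Coord:
        if self.kind == "node":
            return ("H", self.index)
        return ("J", *self.index)  # type: ignore[misc]


@dataclass(frozen=True)
class TreatmentSpec:
    """Which element(s) to treat, by how much, and their flexibility.

    ``fix_treated`` freezes the treated coordinate(s) during recovery
    (the default: the externally imposed change persists).  With
    ``dissection`` the targeted edges are cut — set to exactly 0 and
    always frozen — regardless of alpha.
    """

    targets: tuple[Target, ...]
    fix_treated: bool = True
    dissection: bool = False

    def __post_init__(self) -> None:
        targets = tuple(
            t if isinstance(t, Target) else Target(*t) for t in self.targets
        )
        if self.dissection and any(t.kind != "edge" for t in targets):
            raise ValueError("dissection applies to edge targets only")
        object.__setattr__(self, "targets", targets)

    @classmethod
    def node(cls, index: int, alpha: float, **kw) -> "TreatmentSpec":
        return cls(targets=(Target("node", index, alpha),), **kw)

    @classmethod
    def edge(cls, i: int, j: int, alpha: float, **kw) -> "TreatmentSpec":
        return cls(targets=(Target("edge", (i, j), alpha),), **kw)

    @classmethod
    def dissect(cls, edges: Iterable[tuple[int, int]]) -> "TreatmentSpec":
        return cls(
            targets=tuple(Target("edge", e, 0.0) for e in edges),
            dissection=True,
        )

    def treated_coords(self) -> set[Coord]:
        return {t.coord() for t in self.targets}


@dataclass(frozen=True)
class RecoveryConfig:
    """Hyperparameters of the restoration dynamic.

    neighbor_threshold : float
        |J_ij| >= threshold marks an edge "strongly connected" and hence
        part of the recovering neighbor set (default 0.1).
    learning_rate : float
        a_g of the log-moment-matching updates (default 0.2).
    step_cap_fraction : float
        Each coordinate's applied change per step is capped at this
        fraction of its previous-step change (default 0.2, i.e. <20%).
    cap_mode : str
        "prev_delta" caps against the previous applied change (with a
        small floor so updates never freeze entirely);
        "fraction_of_value" caps against the coordinate's current
        magnitude instead.
    bound_fraction : float
        Half-width of the flexibility box: each recovering parameter
        stays within ``bound_fraction * max(|pre value|, 0.1)`` of its
        pre-treatment value (default 1.0 = ±100%).
    saturation_tol, saturation_window :
        Restoration is saturated when the relative change of the
        distance D_r stays below ``saturation_tol`` for
        ``saturation_window`` consecutive iterations.
    noise_sd : float
        Standard deviation of Gaussian noise added to every applied
        change; 0 (default) gives the deterministic dynamic.
    """

    neighbor_threshold: float = 0.1
    learning_rate: float = 0.2
    step_cap_fraction: float = 0.2
    cap_mode: str = "prev_delta"
    bound_fraction: float = 1.0
    saturation_tol: float = 1e-4
    saturation_window: int = 5
    max_iters: int = 500
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.step_cap_fraction <= 1.0:
            raise ValueError("step_cap_fraction must be in (0, 1]")
        if self.cap_mode not in ("prev_delta", "fraction_of_value"):
            raise ValueError(f"unknown cap_mode {self.cap_mode!r}")
        for name in ("learning_rate", "bound_fraction", "saturation_tol"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass(frozen=True)
class RecoveryTrace:
    """Trajectory of one restoration run.

    ``params_per_iter[0]`` is the treated system (iteration 0);
    ``d_curve[t]`` and ``rmsd_curve[t]`` measure ``params_per_iter[t]``
    against the pre-treatment reference.
    """

    params_per_iter: tuple[SystemParams, ...]
    d_curve: np.ndarray
    rmsd_curve: np.ndarray
    saturated_at: int | None
    neighbor_coords: tuple[Coord, ...]
    pre: SystemParams
    support: frozenset[int] | None

    @property
    def final(self) -> SystemParams:
        return self.params_per_iter[-1]

    @property
    def n_iters(self) -> int:
        return len(self.params_per_iter) - 1

    @property
    def saturated(self) -> bool:
        return self.saturated_at is not None


class RecoveryDiverged(RuntimeError):
    """Restoration ran away from the reference; carries the partial trace."""

    def __init__(self, message: str, trace: RecoveryTrace):
        super().__init__(message)
        self.trace = trace


def apply_treatment(pre: SystemParams, spec: TreatmentSpec) -> SystemParams:
    """Impose the treatment: shift each targeted coordinate by its alpha.

    Node targets add alpha to H_i; edge targets add alpha to J_ij (both
    triangles, keeping J symmetric).  Dissection sets the edge to
    exactly 0.  Every other coordinate is bit-identical to ``pre``.
    """
    h, j = pre.copy_arrays()
    n = pre.n_regions
    for t in spec.targets:
        if t.kind == "node":
            i = t.index
            if not 0 <= i < n:
                raise IndexError(f"node index {i} out of range for N={n}")
            h[i] += t.alpha
        else:
            a, b = t.index  # type: ignore[misc]
            if not (0 <= a < n and 0 <= b < n):
                raise IndexError(f"edge {t.index} out of range for N={n}")
            if spec.dissection:
                j[a, b] = j[b, a] = 0.0
            else:
                j[a, b] += t.alpha
                j[b, a] += t.alpha
    return pre.replace(h=h, j=j)


def neighbor_set(
    params: SystemParams,
    spec: TreatmentSpec,
    threshold: float = 0.1,
) -> list[Coord]:
    """Parameter coordinates that participate in restoration.

    For a treated node m: the edges strongly connected to it,
    {J_mk : |J_mk| >= threshold}.  For a treated edge (i, j): the two
    endpoint sensitivities H_i, H_j plus the strongly connected edges of
    both endpoints.  Unions over multiple targets; treated coordinates
    are excluded when ``fix_treated`` (dissected edges always are).
    """
    n = params.n_regions
    coords: set[Coord] = set()
    for t in spec.targets:
        if t.kind == "node":
            m = t.index
            for k in range(n):
                if k != m and abs(params.j[m, k]) >= threshold:
                    coords.add(("J", min(m, k), max(m, k)))
        else:
            a, b = t.index  # type: ignore[misc]
            coords.add(("H", a))
            coords.add(("H", b))
            for end in (a, b):
                for k in range(n):
                    if k != end and abs(params.j[end, k]) >= threshold:
                        coords.add(("J", min(end, k), max(end, k)))
    if spec.fix_treated or spec.dissection:
        coords -= spec.treated_coords()
    out = sorted(coords)
    if not out:
        warnings.warn(
            "neighbor set is empty; restoration will be a no-op",
            stacklevel=2,
        )
    return out


def _coord_value(h: np.ndarray, j: np.ndarray, c: Coord) -> float:
    if c[0] == "H":
        return h[c[1]]
    return j[c[1], c[2]]


def _moment(mean_act: np.ndarray, mean_coact: np.ndarray, c: Coord) -> float:
    if c[0] == "H":
        m = mean_act[c[1]]
    else:
        m = mean_coact[c[1], c[2]]
    return max(float(m), _LOG_FLOOR)


def recovery_step(
    current: SystemParams,
    pre: SystemParams,
    neighbors: Sequence[Coord],
    cfg: RecoveryConfig,
    prev_delta: np.ndarray | None = None,
    pre_moments: tuple[np.ndarray, np.ndarray] | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[SystemParams, np.ndarray]:
    """One restoration update on the neighbor coordinates.

    Returns the updated system and the vector of applied changes (one
    entry per neighbor coordinate, in the order given), which feeds the
    next step's cap.  Coordinates outside ``neighbors`` are untouched.
    """
    if pre_moments is None:
        pre_moments = expectations(pre)
    cur_act, cur_coact = expectations(current)
    pre_act, pre_coact = pre_moments

    h, j = current.copy_arrays()
    applied = np.zeros(len(neighbors))
    for idx, c in enumerate(neighbors):
        m_pre = _moment(pre_act, pre_coact, c)
        m_cur = _moment(cur_act, cur_coact, c)
        delta = cfg.learning_rate * (np.log(m_pre) - np.log(m_cur))
        if cfg.cap_mode == "prev_delta":
            if prev_delta is not None:
                cap = cfg.step_cap_fraction * abs(prev_delta[idx]) + _CAP_FLOOR
                delta = np.clip(delta, -cap, cap)
        else:  # fraction_of_value
            cap = cfg.step_cap_fraction * max(
                abs(_coord_value(h, j, c)), 0.1
            )
            delta = np.clip(delta, -cap, cap)
        if cfg.noise_sd > 0:
            if rng is None:
                rng = np.random.default_rng(cfg.seed)
            delta += rng.normal(0.0, cfg.noise_sd)
        ref = _coord_value(pre.h, pre.j, c)
        half = cfg.bound_fraction * max(abs(ref), 0.1)
        old = _coord_value(h, j, c)
        new = float(np.clip(old + delta, ref - half, ref + half))
        applied[idx] = new - old
        if c[0] == "H":
            h[c[1]] = new
        else:
            j[c[1], c[2]] = new
            j[c[2], c[1]] = new
    return current.replace(h=h, j=j), applied


def run_recovery(
    treated: SystemParams,
    pre: SystemParams,
    spec: TreatmentSpec,
    cfg: RecoveryConfig = RecoveryConfig(),
    support: Iterable[int] | None = None,
) -> RecoveryTrace:
    """Iterate the restoration dynamic from the treated system.

    Records the functional distance D_r = partial KL(pre, current) over
    ``support`` and the RMSD of J from ``pre`` at every iteration, and
    stops when D_r has stopped improving (relative change below
    ``cfg.saturation_tol`` for ``cfg.saturation_window`` consecutive
    iterations) or at ``cfg.max_iters``.  The support defaults to the
    basins of ``pre``'s top-5 attractors.
    """
    from .distances import default_support  # local: avoids cycle at import

    if support is None:
        support = default_support(pre)
    support = frozenset(int(s) for s in support)
    neighbors = tuple(
        neighbor_set(pre, spec, threshold=cfg.neighbor_threshold)
    )
    rng = np.random.default_rng(cfg.seed) if cfg.noise_sd > 0 else None
    pre_moments = expectations(pre)

    current = treated
    d0 = partial_kl(pre, current, support)
    d_curve = [d0]
    rmsd_curve = [rmsd(pre, current, which="J")]
    systems = [current]

    if not neighbors or current == pre:
        return RecoveryTrace(
            params_per_iter=tuple(systems),
            d_curve=np.asarray(d_curve),
            rmsd_curve=np.asarray(rmsd_curve),
            saturated_at=0,
            neighbor_coords=neighbors,
            pre=pre,
            support=support,
        )

    prev_delta: np.ndarray | None = None
    flat_run = 0
    frozen_run = 0
    bad_run = 0
    saturated_at: int | None = None
    for it in range(1, cfg.max_iters + 1):
        current, prev_delta = recovery_step(
            current, pre, neighbors, cfg,
            prev_delta=prev_delta, pre_moments=pre_moments, rng=rng,
        )
        d = partial_kl(pre, current, support)
        systems.append(current)
        d_curve.append(d)
        rmsd_curve.append(rmsd(pre, current, which="J"))

        rel = abs(d - d_curve[-2]) / max(abs(d_curve[-2]), 1e-15)
        flat_run = flat_run + 1 if rel < cfg.saturation_tol else 0
        # the step cap's floor lets parameters crawl indefinitely; once
        # every applied change sits at that floor nothing significant
        # can improve any more, which is saturation in practice
        frozen = np.abs(prev_delta).max() <= 5.0 * _CAP_FLOOR
        frozen_run = frozen_run + 1 if frozen else 0
        if (flat_run >= cfg.saturation_window
                or frozen_run >= cfg.saturation_window):
            saturated_at = it
            break

        bad_run = bad_run + 1 if (d > 10.0 * max(d0, 1e-12)) else 0
        if bad_run >= cfg.saturation_window:
            trace = RecoveryTrace(
                tuple(systems), np.asarray(d_curve), np.asarray(rmsd_curve),
                None, neighbors, pre, support,
            )
            raise RecoveryDiverged(
                f"distance grew to {d:.3g} (>10x initial {d0:.3g}) for "
                f"{cfg.saturation_window} consecutive iterations", trace,
            )

    return RecoveryTrace(
        params_per_iter=tuple(systems),
        d_curve=np.asarray(d_curve),
        rmsd_curve=np.asarray(rmsd_curve),
        saturated_at=saturated_at,
        neighbor_coords=neighbors,
        pre=pre,
        support=support,
    )


def stabilize(trace: RecoveryTrace) -> SystemParams:
    """Promote a saturated recovery to the new pre-treatment reference.

    A transient (unsaturated) system does not represent a stable
    adaptation to the environment's demands and is refused; subsequent
    treatments must keep referring to the last stabilized system.
    """
    if not trace.saturated:
        raise ValueError(
            "recovery has not saturated; a transient system cannot become "
            "the new pre-treatment reference"
        )
    return trace.final
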