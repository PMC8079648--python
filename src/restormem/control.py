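"""Restoration-aware optimal treatment search.

Given a source system (e.g. a diseased network) and a goal system whose
dynamics we want to induce, the control problem is to pick treatment
targets (nodes or edges), strengths alpha, and timings so that — *after
the system's own self-restoration has run its course* — the functional
distance D+ from the goal's microstate dynamics is minimal.  All
searches are exhaustive grid searches; the restoration dynamic is
simulated for every candidate, which is what distinguishes these plans
from the naive choice that scores the immediate post-treatment system.

Searches provided: a single treatment, repeated treatments at one node
applied at saturation, repeated treatments with flexible timing
(treating the transient, partially recovered system), and dissection of
interhemispheric edges (callosotomy-style, J set to 0 and frozen).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .distances import default_support, partial_kl
from .params import SystemParams
from .restoration import (
    RecoveryConfig,
    RecoveryTrace,
    Target,
    TreatmentSpec,
    apply_treatment,
    run_recovery,
    stabilize,
)

__all__ = [
    "ControlProblem",
    "ControlResult",
    "apply_treatment",
    "evaluate_without_restoration",
    "optimize_single",
    "optimize_naive",
    "optimize_repetitive",
    "optimize_timed",
    "enumerate_dissection_candidates",
    "optimize_dissection",
]

_DEFAULT_STRENGTHS = tuple(
    round(s * a, 10)
    for a in [0.05 * k for k in range(1, 11)]
    for s in (+1.0, -1.0)
)


@dataclass(frozen=True)
class ControlProblem:
    """A source system, a goal system, and the search grids.

    ``candidate_targets`` holds node indices (ints) and/or edge pairs;
    ``None`` means every node.  ``strength_grid`` are the candidate
    alphas (both signs, default ±0.05..±0.50).  ``timing_grid`` entries
    are fractions of the full-recovery time at which the next treatment
    may be applied (1.0 = wait for saturation).
    """

    source: SystemParams
    goal: SystemParams
    candidate_targets: tuple | None = None
    strength_grid: tuple[float, ...] = _DEFAULT_STRENGTHS
    timing_grid: tuple[float, ...] = (1.0,)
    max_treatments: int = 1
    k_major: int = 5
    recovery: RecoveryConfig = field(default_factory=RecoveryConfig)
    left_regions: tuple[int, ...] | None = None
    right_regions: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if self.source.n_regions != self.goal.n_regions:
            raise ValueError("source and goal differ in size")
        if not self.strength_grid:
            raise ValueError("strength grid is empty")
        if not self.timing_grid:
            raise ValueError("timing grid is empty")
        targets = self.candidate_targets
        if targets is None:
            targets = tuple(range(self.source.n_regions))
        object.__setattr__(self, "candidate_targets", tuple(targets))

    def goal_support(self) -> frozenset[int]:
        """KL support: basins of the goal system's major attractors."""
        return default_support(self.goal, k_major=self.k_major)


@dataclass(frozen=True)
class ControlResult:
    """Outcome of a treatment search.

    ``plan`` lists the applied treatments in order as
    (target, alpha, timing) where timing is the fraction of the previous
    recovery waited before treating.  ``table`` scores every evaluated
    candidate; the reported ``best_dplus`` is its minimum for the
    winning plan.  The curves trace the whole realized
    treatment-and-recovery history of the winning plan.
    """

    plan: tuple[tuple[Target, float], ...]
    table: pd.DataFrame
    best_dplus: float
    distance_to_goal_curve: np.ndarray
    distance_to_pre_curve: np.ndarray
    final_system: SystemParams


def _as_spec(target, alpha: float) -> TreatmentSpec:
    if isinstance(target, (int, np.integer)):
        return TreatmentSpec.node(int(target), alpha)
    return TreatmentSpec.edge(int(target[0]), int(target[1]), alpha)


def _target_key(target) -> tuple:
    """Sort key: nodes before edges, then by index."""
    if isinstance(target, (int, np.integer)):
        return (0, int(target))
    return (1, int(target[0]), int(target[1]))


def _goal_curve(problem, trace: RecoveryTrace, support) -> np.ndarray:
    return np.array(
        [partial_kl(problem.goal, p, support)
         for p in trace.params_per_iter]
    )


def evaluate_without_restoration(
    problem: ControlProblem, target, alpha: float,
    support: frozenset[int] | None = None,
) -> float:
    """D+ of the treated system immediately after treatment.

    The naive objective: score the treatment as if the network stayed
    where the treatment put it, simulating no self-restoration.
    """
    if support is None:
        support = problem.goal_support()
    treated = apply_treatment(problem.source, _as_spec(target, alpha))
    return partial_kl(problem.goal, treated, support)


def optimize_single(problem: ControlProblem) -> ControlResult:
    """Exhaustive (target, alpha) grid search scored after full recovery.

    Every candidate treatment is applied to the source, its restoration
    is simulated to saturation with the source as the pre-treatment
    reference, and the candidate is scored by the final D+ from the
    goal.  Ties break to smaller |alpha|, then lower target index.
    """
    support = problem.goal_support()
    pre_support = default_support(problem.source, k_major=problem.k_major)
    rows = []
    best = None
    for target in problem.candidate_targets:
        for alpha in problem.strength_grid:
            spec = _as_spec(target, alpha)
            treated = apply_treatment(problem.source, spec)
            trace = run_recovery(
                treated, problem.source, spec, problem.recovery,
                support=pre_support,
            )
            dplus = partial_kl(problem.goal, trace.final, support)
            rows.append({"target": target, "alpha": alpha,
                         "timing": 1.0, "final_dplus": dplus})
            key = (dplus, abs(alpha), _target_key(target))
            if best is None or key < best[0]:
                best = (key, spec, trace)
    _, spec, trace = best
    return ControlResult(
        plan=((spec.targets[0], 1.0),),
        table=pd.DataFrame(rows),
        best_dplus=float(best[0][0]),
        distance_to_goal_curve=_goal_curve(problem, trace, support),
        distance_to_pre_curve=trace.d_curve,
        final_system=trace.final,
    )


def optimize_naive(problem: ControlProblem) -> ControlResult:
    """Grid search that ignores restoration, then realize the chosen plan.

    The candidate minimizing the *immediate* post-treatment D+ is
    chosen; the returned distances and final system nevertheless include
    the self-restoration that the real system would undergo, so the
    result is directly comparable with `optimize_single`.
    """
    support = problem.goal_support()
    pre_support = default_support(problem.source, k_major=problem.k_major)
    rows = []
    best = None
    for target in problem.candidate_targets:
        for alpha in problem.strength_grid:
            d_now = evaluate_without_restoration(
                problem, target, alpha, support
            )
            rows.append({"target": target, "alpha": alpha,
                         "timing": 1.0, "immediate_dplus": d_now})
            key = (d_now, abs(alpha), _target_key(target))
            if best is None or key < best[0]:
                best = (key, target, alpha)
    _, target, alpha = best
    spec = _as_spec(target, alpha)
    treated = apply_treatment(problem.source, spec)
    trace = run_recovery(
        treated, problem.source, spec, problem.recovery, support=pre_support
    )
    realized = partial_kl(problem.goal, trace.final, support)
    return ControlResult(
        plan=((spec.targets[0], 1.0),),
        table=pd.DataFrame(rows),
        best_dplus=float(realized),
        distance_to_goal_curve=_goal_curve(problem, trace, support),
        distance_to_pre_curve=trace.d_curve,
        final_system=trace.final,
    )


def _greedy_rounds(
    problem: ControlProblem,
    target,
    support: frozenset[int],
    improvement_tol: float = 1e-9,
) -> tuple[list, list[RecoveryTrace], SystemParams, list[dict]]:
    """Greedy saturated-timing rounds on one fixed target."""
    stab = problem.source
    plan, traces, rows = [], [], []
    current_d = partial_kl(problem.goal, stab, support)
    for rnd in range(problem.max_treatments):
        pre_support = default_support(stab, k_major=problem.k_major)
        best = None
        for alpha in problem.strength_grid:
            spec = _as_spec(target, alpha)
            treated = apply_treatment(stab, spec)
            trace = run_recovery(
                treated, stab, spec, problem.recovery, support=pre_support
            )
            dplus = partial_kl(problem.goal, trace.final, support)
            rows.append({"target": target, "round": rnd, "alpha": alpha,
                         "timing": 1.0, "final_dplus": dplus})
            key = (dplus, abs(alpha))
            if best is None or key < best[0]:
                best = (key, spec, trace)
        (d_best, _), spec, trace = best
        if d_best >= current_d - improvement_tol:
            break  # no round improves: stop treating
        plan.append((spec.targets[0], 1.0))
        traces.append(trace)
        stab = stabilize(trace)
        current_d = d_best
    return plan, traces, stab, rows


def optimize_repetitive(
    problem: ControlProblem, target=None
) -> ControlResult:
    """Repeated treatments at one node, each applied at saturation.

    Greedy: per round the strength grid is re-searched on the fixed
    target, the best treatment applied, its recovery run to saturation,
    and the recovered system stabilized as the reference for the next
    round.  Rounds stop at ``max_treatments`` or when no strength
    improves the distance to goal.  With ``target=None`` the whole
    procedure is run for every candidate target and the best is kept.
    """
    support = problem.goal_support()
    targets = (
        problem.candidate_targets if target is None else (target,)
    )
    all_rows: list[dict] = []
    best = None
    for tgt in targets:
        plan, traces, stab, rows = _greedy_rounds(problem, tgt, support)
        all_rows.extend(rows)
        final_d = partial_kl(problem.goal, stab, support)
        key = (final_d, _target_key(tgt))
        if best is None or key < best[0]:
            best = (key, plan, traces, stab)
    _, plan, traces, stab = best
    goal_curve, pre_curve = _concat_curves(problem, traces, support)
    return ControlResult(
        plan=tuple(plan),
        table=pd.DataFrame(all_rows),
        best_dplus=float(best[0][0]),
        distance_to_goal_curve=goal_curve,
        distance_to_pre_curve=pre_curve,
        final_system=stab,
    )


def _concat_curves(problem, traces, support):
    if not traces:
        d = partial_kl(problem.goal, problem.source, support)
        return np.array([d]), np.array([0.0])
    goal_parts, pre_parts = [], []
    for tr in traces:
        goal_parts.append(_goal_curve(problem, tr, support))
        pre_parts.append(tr.d_curve)
    return np.concatenate(goal_parts), np.concatenate(pre_parts)


def optimize_timed(problem: ControlProblem, target=None) -> ControlResult:
    """Repeated treatments with flexible timing of each application.

    From the second round on, the grid runs over (alpha, T): T is the
    fraction of the previous recovery's saturation time waited before
    treating.  Treating at T < 1 hits a transient system; the
    pre-treatment reference for the interrupted recovery then stays the
    last *stabilized* system (a transient does not satisfy the
    environment's demands).  The saturated-timing plan (all T = 1) is
    always among the evaluated candidates, so adding finer timings can
    only improve the reported best.
    """
    support = problem.goal_support()
    targets = (
        problem.candidate_targets if target is None else (target,)
    )
    all_rows: list[dict] = []
    best = None
    for tgt in targets:
        plan, traces, final_sys, rows = _timed_rounds(
            problem, tgt, support
        )
        all_rows.extend(rows)
        final_d = partial_kl(problem.goal, final_sys, support)
        key = (final_d, _target_key(tgt))
        if best is None or key < best[0]:
            best = (key, tgt, plan, traces, final_sys)

        # the pure saturated-timing greedy plan is a valid timed plan;
        # keep it in the comparison so a finer grid never hurts
        plan_s, traces_s, stab_s, rows_s = _greedy_rounds(
            problem, tgt, support
        )
        for r in rows_s:
            all_rows.append(r)
        d_s = partial_kl(problem.goal, stab_s, support)
        key_s = (d_s, _target_key(tgt))
        if key_s < best[0]:
            best = (key_s, tgt, plan_s, traces_s, stab_s)

    _, tgt, plan, traces, final_sys = best
    goal_curve, pre_curve = _concat_curves(problem, traces, support)
    return ControlResult(
        plan=tuple(plan),
        table=pd.DataFrame(all_rows),
        best_dplus=float(best[0][0]),
        distance_to_goal_curve=goal_curve,
        distance_to_pre_curve=pre_curve,
        final_system=final_sys,
    )


def _timed_rounds(problem, target, support, improvement_tol: float = 1e-9):
    stab = problem.source          # last stabilized reference
    ongoing: RecoveryTrace | None = None
    plan, traces, rows = [], [], []
    current_d = partial_kl(problem.goal, stab, support)
    for rnd in range(problem.max_treatments):
        timings = (1.0,) if ongoing is None else problem.timing_grid
        best = None
        for timing in timings:
            if ongoing is None:
                start, ref = stab, stab
            else:
                t_sat = ongoing.saturated_at or ongoing.n_iters
                cut = min(math.ceil(timing * t_sat), ongoing.n_iters)
                start = ongoing.params_per_iter[cut]
                # full wait => previous recovery stabilized first
                ref = ongoing.final if timing >= 1.0 else stab
            pre_support = default_support(ref, k_major=problem.k_major)
            for alpha in problem.strength_grid:
                spec = _as_spec(target, alpha)
                treated = apply_treatment(start, spec)
                trace = run_recovery(
                    treated, ref, spec, problem.recovery,
                    support=pre_support,
                )
                dplus = partial_kl(problem.goal, trace.final, support)
                rows.append({"target": target, "round": rnd,
                             "alpha": alpha, "timing": timing,
                             "final_dplus": dplus})
                key = (dplus, abs(alpha), timing)
                if best is None or key < best[0]:
                    best = (key, spec, trace, timing)
        (d_best, _, _), spec, trace, timing = best
        if d_best >= current_d - improvement_tol:
            break
        if ongoing is not None and timing >= 1.0:
            stab = ongoing.final
        plan.append((spec.targets[0], timing))
        if ongoing is not None:
            # keep only the realized part of the interrupted recovery
            t_sat = ongoing.saturated_at or ongoing.n_iters
            cut = min(math.ceil(timing * t_sat), ongoing.n_iters)
            traces[-1] = _truncate(ongoing, cut)
        traces.append(trace)
        ongoing = trace
        current_d = d_best
    if ongoing is not None and ongoing.saturated:
        stab = ongoing.final
    final_sys = ongoing.final if ongoing is not None else stab
    return plan, traces, final_sys, rows


def _truncate(trace: RecoveryTrace, cut: int) -> RecoveryTrace:
    return replace(
        trace,
        params_per_iter=trace.params_per_iter[: cut + 1],
        d_curve=trace.d_curve[: cut + 1],
        rmsd_curve=trace.rmsd_curve[: cut + 1],
        saturated_at=trace.saturated_at if (
            trace.saturated_at is not None and trace.saturated_at <= cut
        ) else None,
    )


def enumerate_dissection_candidates(
    left_regions, right_regions, k: int, counting: str = "unordered"
) -> list[tuple]:
    """All selections of k distinct interhemispheric edges.

    Candidate edges are every left x right pair.  ``"unordered"``
    (default) yields each physical edge set once (k-combinations);
    ``"ordered"`` yields k-permutations, the convention under which 7x7
    hemispheres give 49, 2352 and 110544 selections for k = 1, 2, 3.
    """
    edges = [
        (int(l), int(r)) for l in left_regions for r in right_regions
    ]
    if k < 1 or k > len(edges):
        raise ValueError(f"k={k} out of range for {len(edges)} edges")
    if counting == "ordered":
        return list(itertools.permutations(edges, k))
    if counting == "unordered":
        return list(itertools.combinations(edges, k))
    raise ValueError(f"counting must be 'ordered' or 'unordered'")


def optimize_dissection(problem: ControlProblem, k: int) -> ControlResult:
    """Best set of k interhemispheric edges to cut.

    Every unordered k-set of left x right edges is dissected (J = 0,
    frozen), the neighbors' restoration simulated to saturation, and the
    set scored by final D+ from the goal.  The per-candidate table holds
    the full distribution of final distances (box-plot data).
    """
    if problem.left_regions is None or problem.right_regions is None:
        raise ValueError("problem needs left_regions and right_regions")
    support = problem.goal_support()
    pre_support = default_support(problem.source, k_major=problem.k_major)
    sets = enumerate_dissection_candidates(
        problem.left_regions, problem.right_regions, k, "unordered"
    )
    rows = []
    best = None
    for edges in sets:
        spec = TreatmentSpec.dissect(edges)
        treated = apply_treatment(problem.source, spec)
        trace = run_recovery(
            treated, problem.source, spec, problem.recovery,
            support=pre_support,
        )
        dplus = partial_kl(problem.goal, trace.final, support)
        rows.append({"edges": edges, "final_dplus": dplus})
        key = (dplus, edges)
        if best is None or key < best[0]:
            best = (key, spec, trace)
    _, spec, trace = best
    return ControlResult(
        plan=tuple((t, 1.0) for t in spec.targets),
        table=pd.DataFrame(rows),
        best_dplus=float(best[0][0]),
        distance_to_goal_curve=_goal_curve(problem, trace, support),
        distance_to_pre_curve=trace.d_curve,
        final_system=trace.final,
    )
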