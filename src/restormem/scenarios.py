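"""End-to-end scenario runners for the six study simulations.

Each runner builds its inputs from the synthetic bilateral system,
executes the method (treat -> restore -> optionally optimize) and
returns a JSON-ready bundle of curves and summary numbers.  All runs
are pure functions of the seed.  The default scenario grids are reduced
(strengths ±{0.1, 0.25, 0.5}) so a full scenario suite runs at desk
scale; pass ``strength_grid`` explicitly for the full ±{0.05..0.50}
grid.

Scenarios
---------
sim1  self-restoration after one node treatment (degeneracy pattern)
sim2  recovery capacity vs number of neighbors, per node and edge
sim3  restoration-aware vs naive single-treatment control
sim4  repetitive treatment at a single node, applied at saturation
sim5  repetitive treatment with flexible timing
sim6  optimal dissection of interhemispheric edges (virtual callosotomy)
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from scipy import stats

from .control import (
    ControlProblem,
    optimize_dissection,
    optimize_naive,
    optimize_repetitive,
    optimize_single,
    optimize_timed,
    enumerate_dissection_candidates,
)
from .distances import default_support, partial_kl, recovery_capacity
from .landscape import assign_basins, export_landscape
from .params import SystemParams
from .restoration import (
    RecoveryConfig,
    TreatmentSpec,
    apply_treatment,
    neighbor_set,
    run_recovery,
)
from .synthetic import (
    SyntheticSpec,
    make_bilateral_system,
    perturb_system,
    strengthen_interhemispheric,
)

__all__ = ["run_scenario", "SCENARIOS", "REDUCED_GRID"]

#: Reduced strength grid used by the scenario runners.
REDUCED_GRID = (0.1, -0.1, 0.25, -0.25, 0.5, -0.5)

#: Node treated in sim1 (the right-thalamus analog of the bilateral system).
SIM1_NODE = 13

#: Fixed treatment strength used in the capacity sweep (sim2).
SIM2_ALPHA = 0.5


def _base_system(seed: int) -> SystemParams:
    return make_bilateral_system(SyntheticSpec(seed=seed))


def sim1(seed: int = 0, node: int = SIM1_NODE, alpha: float = 0.5,
         cfg: RecoveryConfig = RecoveryConfig()) -> dict:
    """Self-restoration after adding ``alpha`` to one node's H.

    Shows the degeneracy pattern: the functional distance to the
    pre-treatment system falls during restoration while the J-parameter
    distance grows.
    """
    pre = _base_system(seed)
    spec = TreatmentSpec.node(node, alpha)
    treated = apply_treatment(pre, spec)
    support = default_support(pre)
    trace = run_recovery(treated, pre, spec, cfg, support=support)
    ls_pre = assign_basins(pre)
    ls_final = assign_basins(trace.final)
    return {
        "scenario": "sim1", "seed": seed, "node": node, "alpha": alpha,
        "d_curve": trace.d_curve.tolist(),
        "rmsd_j_curve": trace.rmsd_curve.tolist(),
        "saturated_at": trace.saturated_at,
        "d_treated": float(trace.d_curve[0]),
        "d_final": float(trace.d_curve[-1]),
        "rmsd_j_final": float(trace.rmsd_curve[-1]),
        "n_neighbors": len(trace.neighbor_coords),
        "landscape_pre": export_landscape(ls_pre),
        "landscape_final": export_landscape(ls_final),
    }


def sim2(seed: int = 0, alpha: float = SIM2_ALPHA, n_edges: int = 10,
         cfg: RecoveryConfig = RecoveryConfig()) -> dict:
    """Recovery capacity of every node (and a sample of edges) vs the
    number of neighbors participating in restoration."""
    pre = _base_system(seed)
    support = default_support(pre)
    n = pre.n_regions

    def capacity(spec: TreatmentSpec) -> tuple[int, float]:
        nbrs = neighbor_set(pre, spec, cfg.neighbor_threshold)
        treated = apply_treatment(pre, spec)
        trace = run_recovery(treated, pre, spec, cfg, support=support)
        dcap = recovery_capacity(pre, treated, trace.final, support)
        return len(nbrs), float(dcap)

    nodes = []
    for m in range(n):
        k, dcap = capacity(TreatmentSpec.node(m, alpha))
        nodes.append({"node": m, "n_neighbors": k, "delta_d": dcap})

    iu = np.transpose(np.triu_indices(n, k=1))
    strong = [(int(a), int(b)) for a, b in iu if abs(pre.j[a, b]) >= 0.1]
    rng = np.random.default_rng(seed)
    pick = rng.choice(len(strong), size=min(n_edges, len(strong)),
                      replace=False)
    edges = []
    for t in sorted(pick):
        a, b = strong[t]
        k, dcap = capacity(TreatmentSpec.edge(a, b, alpha))
        edges.append({"edge": [a, b], "n_neighbors": k, "delta_d": dcap})

    rho_nodes = stats.spearmanr(
        [r["n_neighbors"] for r in nodes], [r["delta_d"] for r in nodes]
    ).statistic
    rho_edges = stats.spearmanr(
        [r["n_neighbors"] for r in edges], [r["delta_d"] for r in edges]
    ).statistic if len(edges) > 2 else float("nan")
    return {
        "scenario": "sim2", "seed": seed, "alpha": alpha,
        "nodes": nodes, "edges": edges,
        "spearman_nodes": float(rho_nodes),
        "spearman_edges": float(rho_edges),
    }


def sim3(seed: int = 0, strength_grid=REDUCED_GRID,
         cfg: RecoveryConfig = RecoveryConfig()) -> dict:
    """Single-treatment control, with vs without the restoration model.

    The goal is the healthy bilateral system; the source is its
    Gaussian-perturbed (sd 0.1) diseased variant.  Both searches share
    the grid; the naive plan is chosen on the immediate post-treatment
    distance and then realized under restoration.
    """
    goal = _base_system(seed)
    source = perturb_system(goal, sd=0.1, seed=seed + 1)
    problem = ControlProblem(
        source=source, goal=goal, strength_grid=tuple(strength_grid),
        recovery=cfg,
    )
    aware = optimize_single(problem)
    naive = optimize_naive(problem)
    d0 = partial_kl(goal, source, problem.goal_support())
    return {
        "scenario": "sim3", "seed": seed,
        "d_source_to_goal": float(d0),
        "aware": _result_summary(aware),
        "naive": _result_summary(naive),
    }


def _result_summary(res) -> dict:
    return {
        "plan": [
            {"kind": t.kind, "index": t.index, "alpha": t.alpha,
             "timing": timing}
            for t, timing in res.plan
        ],
        "final_dplus": float(res.best_dplus),
        "distance_to_goal_curve": res.distance_to_goal_curve.tolist(),
        "distance_to_pre_curve": res.distance_to_pre_curve.tolist(),
    }


def _sim45_problem(seed, strength_grid, timing_grid, max_treatments, cfg):
    goal = _base_system(seed)
    source = perturb_system(goal, sd=0.1, seed=seed + 1)
    return ControlProblem(
        source=source, goal=goal, strength_grid=tuple(strength_grid),
        timing_grid=tuple(timing_grid), max_treatments=max_treatments,
        recovery=cfg,
    )


def _pick_target(problem: ControlProblem):
    """Fixed node for the repetitive scenarios: best single treatment."""
    single = optimize_single(problem)
    return single.plan[0][0].index, single


def sim4(seed: int = 0, strength_grid=REDUCED_GRID, max_treatments: int = 3,
         cfg: RecoveryConfig = RecoveryConfig()) -> dict:
    """Repetitive treatment of one node, each applied at saturation."""
    problem = _sim45_problem(seed, strength_grid, (1.0,), max_treatments, cfg)
    target, single = _pick_target(problem)
    rep = optimize_repetitive(problem, target=target)
    return {
        "scenario": "sim4", "seed": seed, "target": target,
        "single": _result_summary(single),
        "repetitive": _result_summary(rep),
        "n_treatments": len(rep.plan),
    }


def sim5(seed: int = 0, strength_grid=REDUCED_GRID,
         timing_grid=(0.25, 0.5, 0.75, 1.0), max_treatments: int = 3,
         cfg: RecoveryConfig = RecoveryConfig()) -> dict:
    """Repetitive treatment with flexible timing of each application."""
    problem = _sim45_problem(
        seed, strength_grid, timing_grid, max_treatments, cfg
    )
    target, single = _pick_target(problem)
    rep = optimize_repetitive(problem, target=target)
    timed = optimize_timed(problem, target=target)
    return {
        "scenario": "sim5", "seed": seed, "target": target,
        "repetitive": _result_summary(rep),
        "timed": _result_summary(timed),
        "timing_grid": list(timing_grid),
    }


def sim6(seed: int = 0, k: int = 1,
         cfg: RecoveryConfig = RecoveryConfig()) -> dict:
    """Virtual callosotomy: best interhemispheric edges to dissect.

    The source is the bilateral system with polarity-strengthened
    interhemispheric couplings; the goal is the unmodified system.
    Candidate counts for one, two and three edges are reported in both
    the ordered and unordered conventions.
    """
    goal = _base_system(seed)
    nh = (goal.n_regions - 1) // 2
    left = tuple(range(nh))
    right = tuple(range(nh, 2 * nh))
    source = strengthen_interhemispheric(
        goal, left, right, sd=0.1, seed=seed + 1
    )
    problem = ControlProblem(
        source=source, goal=goal, recovery=cfg,
        left_regions=left, right_regions=right,
    )
    res = optimize_dissection(problem, k=k)
    counts = {
        f"k{kk}": {
            "ordered": len(enumerate_dissection_candidates(
                left, right, kk, "ordered")),
            "unordered": len(enumerate_dissection_candidates(
                left, right, kk, "unordered")),
        }
        for kk in (1, 2, 3)
    }
    d0 = partial_kl(goal, source, problem.goal_support())
    return {
        "scenario": "sim6", "seed": seed, "k": k,
        "candidate_counts": counts,
        "d_source_to_goal": float(d0),
        "best": _result_summary(res),
        "final_dplus_distribution": res.table["final_dplus"].tolist(),
    }


SCENARIOS = {
    "sim1": sim1, "sim2": sim2, "sim3": sim3,
    "sim4": sim4, "sim5": sim5, "sim6": sim6,
}


def run_scenario(name: str, seed: int = 0, outdir: str | None = None,
                 **kwargs) -> dict:
    """Run one named scenario end-to-end; optionally write its bundle.

    Writes ``<name>.json`` (full bundle) and ``<name>_curves.csv`` (the
    main distance curve, when present) under ``outdir``.  Identical
    seeds give byte-identical JSON.
    """
    if name not in SCENARIOS:
        raise ValueError(
            f"unknown scenario {name!r}; choose from {sorted(SCENARIOS)}"
        )
    bundle = SCENARIOS[name](seed=seed, **kwargs)
    if outdir is not None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / f"{name}.json", "w") as fh:
            json.dump(bundle, fh, indent=1, sort_keys=True)
        curve = bundle.get("d_curve") or bundle.get(
            "aware", {}).get("distance_to_goal_curve")
        if curve:
            np.savetxt(out / f"{name}_curves.csv",
                       np.asarray(curve), header="distance", comments="")
    return bundle
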