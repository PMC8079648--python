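"""Restoration-aware treatment search: grids, repetition, timing, dissection."""

import numpy as np
import pytest

from restormem import (
    ControlProblem,
    RecoveryConfig,
    SystemParams,
    TreatmentSpec,
    apply_treatment,
    enumerate_dissection_candidates,
    evaluate_without_restoration,
    optimize_dissection,
    optimize_naive,
    optimize_repetitive,
    optimize_single,
    optimize_timed,
    partial_kl,
)
from restormem.synthetic import (
    SyntheticSpec,
    make_bilateral_system,
    perturb_system,
    strengthen_interhemispheric,
)


@pytest.fixture(scope="module")
def small_problem():
    """4-region problem small enough for exhaustive cross-checks."""
    goal = SystemParams(
        h=[-0.2, -0.1, -0.3, -0.2],
        j=np.array([
            [0.0, 0.4, 0.15, 0.0],
            [0.4, 0.0, 0.0, 0.2],
            [0.15, 0.0, 0.0, 0.35],
            [0.0, 0.2, 0.35, 0.0],
        ]),
    )
    source = perturb_system(goal, sd=0.15, seed=5)
    return ControlProblem(
        source=source, goal=goal,
        strength_grid=(0.1, -0.1, 0.3, -0.3),
    )


class TestEvaluateWithoutRestoration:
    def test_goal_equals_source_zero_alpha(self):
        goal = make_bilateral_system(SyntheticSpec(seed=3))
        prob = ControlProblem(source=goal, goal=goal, strength_grid=(0.1,))
        assert evaluate_without_restoration(prob, 0, 0.0) == pytest.approx(0.0)

    def test_is_composition_of_treat_and_distance(self, small_problem):
        sup = small_problem.goal_support()
        for target, alpha in [(0, 0.3), (2, -0.1), ((1, 3), 0.1)]:
            spec = (
                TreatmentSpec.node(target, alpha)
                if isinstance(target, int)
                else TreatmentSpec.edge(*target, alpha)
            )
            direct = partial_kl(
                small_problem.goal,
                apply_treatment(small_problem.source, spec),
                sup,
            )
            assert evaluate_without_restoration(
                small_problem, target, alpha
            ) == pytest.approx(direct, abs=1e-15)


class TestOptimizeSingle:
    def test_best_matches_table_minimum(self, small_problem):
        res = optimize_single(small_problem)
        assert res.best_dplus == pytest.approx(
            res.table["final_dplus"].min()
        )
        assert len(res.table) == (
            len(small_problem.candidate_targets)
            * len(small_problem.strength_grid)
        )

    def test_goal_equals_source_prefers_zero_alpha(self):
        goal = make_bilateral_system(SyntheticSpec(seed=3))
        prob = ControlProblem(
            source=goal, goal=goal, strength_grid=(0.0, 0.25, -0.25),
            candidate_targets=(0, 5, 13),
        )
        res = optimize_single(prob)
        assert res.plan[0][0].alpha == 0.0
        assert res.best_dplus <= res.table["final_dplus"].min() + 1e-15

    def test_recovers_known_parameter_offset_without_restoration(self):
        # goal differs from source only in H_2 by +0.2; with the
        # neighbor threshold set too high for any recovery, the grid
        # picks node 2 with alpha nearest +0.2
        base = SystemParams(
            h=[-0.1, -0.2, -0.15],
            j=np.array([
                [0.0, 0.3, 0.05],
                [0.3, 0.0, 0.2],
                [0.05, 0.2, 0.0],
            ]),
        )
        goal = base.replace(h=base.h + np.array([0.0, 0.0, 0.2]))
        prob = ControlProblem(
            source=base, goal=goal,
            strength_grid=(0.1, -0.1, 0.2, -0.2, 0.3),
            recovery=RecoveryConfig(neighbor_threshold=10.0),
        )
        with pytest.warns(UserWarning, match="empty"):
            res = optimize_single(prob)
        t, _ = res.plan[0]
        assert (t.kind, t.index, t.alpha) == ("node", 2, 0.2)
        assert res.best_dplus == pytest.approx(0.0, abs=1e-12)

    def test_reproducible_bit_identical(self, small_problem):
        r1 = optimize_single(small_problem)
        r2 = optimize_single(small_problem)
        assert r1.plan == r2.plan
        assert r1.best_dplus == r2.best_dplus
        np.testing.assert_array_equal(
            r1.distance_to_goal_curve, r2.distance_to_goal_curve
        )


class TestRestorationAwareVsNaive:
    def test_aware_never_worse_on_seeded_instances(self):
        goal = make_bilateral_system(SyntheticSpec(seed=1))
        aware_final, naive_final = [], []
        for seed in (11, 12):
            prob = ControlProblem(
                source=perturb_system(goal, 0.1, seed=seed), goal=goal,
                strength_grid=(0.25, -0.25, 0.5, -0.5),
            )
            aware_final.append(optimize_single(prob).best_dplus)
            naive_final.append(optimize_naive(prob).best_dplus)
        assert np.mean(aware_final) <= np.mean(naive_final) + 1e-12


class TestOptimizeRepetitive:
    def test_single_round_matches_optimize_single(self, small_problem):
        from dataclasses import replace

        prob1 = replace(small_problem, max_treatments=1)
        target = optimize_single(prob1).plan[0][0].index
        prob_t = replace(prob1, candidate_targets=(target,))
        rep = optimize_repetitive(prob1, target=target)
        single = optimize_single(prob_t)
        assert rep.best_dplus == pytest.approx(single.best_dplus)
        assert rep.plan[0][0] == single.plan[0][0]

    def test_no_improvement_stops_early(self):
        goal = make_bilateral_system(SyntheticSpec(seed=3))
        prob = ControlProblem(
            source=goal, goal=goal, strength_grid=(0.3, -0.3),
            max_treatments=3,
        )
        res = optimize_repetitive(prob, target=0)
        assert len(res.plan) == 0  # already at the goal: treat nothing
        assert res.final_system == goal


class TestOptimizeTimed:
    def test_degenerate_timing_grid_reduces_to_repetitive(self, small_problem):
        from dataclasses import replace

        prob = replace(
            small_problem, max_treatments=2, timing_grid=(1.0,)
        )
        rep = optimize_repetitive(prob, target=1)
        timed = optimize_timed(prob, target=1)
        assert timed.best_dplus == pytest.approx(rep.best_dplus, abs=1e-15)
        assert timed.plan == rep.plan

    def test_finer_timing_never_worse(self, small_problem):
        from dataclasses import replace

        prob_sat = replace(small_problem, max_treatments=2)
        prob_timed = replace(
            small_problem, max_treatments=2,
            timing_grid=(0.5, 1.0),
        )
        rep = optimize_repetitive(prob_sat, target=1)
        timed = optimize_timed(prob_timed, target=1)
        assert timed.best_dplus <= rep.best_dplus + 1e-12

    def test_timing_bookkeeping_interrupts_at_fraction(self, small_problem):
        from dataclasses import replace

        prob = replace(
            small_problem, max_treatments=2, timing_grid=(0.5,)
        )
        res = optimize_timed(prob, target=1)
        if len(res.plan) == 2:
            assert res.plan[1][1] == 0.5


@pytest.fixture(scope="module")
def toy_callosotomy():
    # 2+2 bilateral toy with strengthened interhemispheric edges
    j = np.zeros((4, 4))
    j[0, 1] = j[1, 0] = 0.4   # left intra
    j[2, 3] = j[3, 2] = 0.4   # right intra
    j[0, 2] = j[2, 0] = 0.3   # homotopic
    j[1, 3] = j[3, 1] = 0.3
    goal = SystemParams(h=np.full(4, -0.25), j=j)
    source = strengthen_interhemispheric(
        goal, (0, 1), (2, 3), sd=0.3, seed=4
    )
    return ControlProblem(
        source=source, goal=goal,
        left_regions=(0, 1), right_regions=(2, 3),
    )


class TestDissection:
    def test_candidate_counts_match_hemisphere_product(self):
        left, right = range(7), range(7, 14)
        assert len(enumerate_dissection_candidates(left, right, 1)) == 49
        assert len(
            enumerate_dissection_candidates(left, right, 2, "ordered")
        ) == 2352
        assert len(
            enumerate_dissection_candidates(left, right, 3, "ordered")
        ) == 110544

    def test_small_unordered_combinations(self):
        sets = enumerate_dissection_candidates([0, 1], [2, 3], 2)
        assert len(sets) == 6

    def test_k_too_large_rejected(self):
        with pytest.raises(ValueError, match="out of range"):
            enumerate_dissection_candidates([0], [1], 2)

    def test_exhaustive_ranking_and_freezing(self, toy_callosotomy):
        res = optimize_dissection(toy_callosotomy, k=1)
        assert len(res.table) == 4
        assert res.best_dplus == pytest.approx(
            res.table["final_dplus"].min()
        )
        t, _ = res.plan[0]
        a, b = t.index
        assert res.final_system.j[a, b] == 0.0

    def test_best_of_k_non_increasing_under_inclusion(self, toy_callosotomy):
        r1 = optimize_dissection(toy_callosotomy, k=1)
        r2 = optimize_dissection(toy_callosotomy, k=2)
        best1 = {t.index for t, _ in r1.plan}
        covered = any(
            best1 <= set(edges) for edges in r2.table["edges"]
        )
        assert covered  # every 1-set extends to some evaluated 2-set
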