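"""Self-restoration dynamics: neighbor sets, constrained updates, traces."""

import numpy as np
import pytest

from restormem import (
    RecoveryConfig,
    SystemParams,
    TreatmentSpec,
    apply_treatment,
    default_support,
    expectations,
    neighbor_set,
    recovery_step,
    run_recovery,
    stabilize,
)
from restormem.synthetic import random_system


def star(n=5, w=0.3):
    j = np.zeros((n, n))
    j[0, 1:] = w
    j[1:, 0] = w
    return SystemParams(h=np.full(n, -0.1), j=j)


class TestNeighborSet:
    def test_hub_treatment_recruits_all_spokes(self):
        p = star()
        spec = TreatmentSpec.node(0, 0.5)
        nbrs = neighbor_set(p, spec, threshold=0.1)
        assert nbrs == [("J", 0, k) for k in range(1, 5)]

    def test_isolated_node_gives_empty_set(self):
        p = star(w=0.05)
        with pytest.warns(UserWarning, match="empty"):
            nbrs = neighbor_set(p, TreatmentSpec.node(0, 0.5), threshold=0.1)
        assert nbrs == []

    def test_edge_treatment_recruits_endpoints_and_their_edges(self):
        p = star()
        spec = TreatmentSpec.edge(0, 1, 0.2)
        nbrs = neighbor_set(p, spec, threshold=0.1)
        # H of both endpoints plus the hub's other spokes; the treated
        # edge itself is frozen by default
        assert ("H", 0) in nbrs and ("H", 1) in nbrs
        assert ("J", 0, 1) not in nbrs
        assert {("J", 0, 2), ("J", 0, 3), ("J", 0, 4)} <= set(nbrs)

    def test_edge_included_when_treated_coordinate_flexible(self):
        p = star()
        spec = TreatmentSpec.edge(0, 1, 0.2, fix_treated=False)
        assert ("J", 0, 1) in neighbor_set(p, spec, threshold=0.1)

    def test_counts_match_brute_force_on_bilateral(self, bilateral):
        for m in range(bilateral.n_regions):
            nbrs = neighbor_set(
                bilateral, TreatmentSpec.node(m, 0.5), threshold=0.1
            )
            expected = sum(
                1 for k in range(bilateral.n_regions)
                if k != m and abs(bilateral.j[m, k]) >= 0.1
            )
            assert len(nbrs) == expected


class TestApplyTreatment:
    def test_zero_alpha_is_identity(self, bilateral):
        out = apply_treatment(bilateral, TreatmentSpec.node(3, 0.0))
        assert out == bilateral

    def test_node_shift_is_exact(self, bilateral):
        out = apply_treatment(bilateral, TreatmentSpec.node(13, 0.5))
        assert out.h[13] == bilateral.h[13] + 0.5
        mask = np.arange(15) != 13
        np.testing.assert_array_equal(out.h[mask], bilateral.h[mask])
        np.testing.assert_array_equal(out.j, bilateral.j)

    def test_edge_shift_keeps_symmetry(self, bilateral):
        out = apply_treatment(bilateral, TreatmentSpec.edge(2, 9, -0.2))
        assert out.j[2, 9] == out.j[9, 2]
        assert out.j[2, 9] == pytest.approx(bilateral.j[2, 9] - 0.2)

    def test_dissection_zeroes_edges(self, bilateral):
        spec = TreatmentSpec.dissect([(0, 7), (1, 8)])
        out = apply_treatment(bilateral, spec)
        assert out.j[0, 7] == out.j[7, 0] == 0.0
        assert out.j[1, 8] == 0.0

    def test_bad_index_rejected(self, bilateral):
        with pytest.raises(IndexError):
            apply_treatment(bilateral, TreatmentSpec.node(99, 0.1))


class TestRecoveryStep:
    def test_fixed_point_at_pre(self):
        p = random_system(4, seed=0)
        nbrs = [("J", 0, 1), ("H", 2)]
        nxt, delta = recovery_step(p, p, nbrs, RecoveryConfig())
        assert nxt == p
        np.testing.assert_array_equal(delta, 0.0)

    def test_first_step_is_exact_log_moment_ratio(self):
        pre = SystemParams(h=[0.2, 0.1], j=[[0, 0.5], [0.5, 0]])
        treated = pre.replace(h=pre.h + np.array([0.5, 0.0]))
        nbrs = [("J", 0, 1)]
        cfg = RecoveryConfig(learning_rate=0.2)
        _, delta = recovery_step(treated, pre, nbrs, cfg)
        _, c_pre = expectations(pre)
        _, c_cur = expectations(treated)
        expected = 0.2 * (np.log(c_pre[0, 1]) - np.log(c_cur[0, 1]))
        assert delta[0] == pytest.approx(expected, abs=1e-15)

    def test_non_neighbors_bit_identical_across_iterations(self):
        pre = random_system(4, seed=3)
        spec = TreatmentSpec.node(0, 0.4)
        treated = apply_treatment(pre, spec)
        nbrs = neighbor_set(pre, spec, threshold=0.1)
        touched = set(nbrs)
        cur, delta = treated, None
        for _ in range(30):
            cur, delta = recovery_step(
                cur, pre, nbrs, RecoveryConfig(), prev_delta=delta
            )
        for i in range(4):
            if ("H", i) not in touched:
                assert cur.h[i] == treated.h[i]
            for k in range(i + 1, 4):
                if ("J", i, k) not in touched:
                    assert cur.j[i, k] == treated.j[i, k]

    def test_flexibility_box_binds(self):
        pre = SystemParams(h=[1.0, -1.0], j=[[0, 0.2], [0.2, 0]])
        treated = pre.replace(h=pre.h + np.array([3.0, 0.0]))
        cfg = RecoveryConfig(learning_rate=50.0, bound_fraction=0.5)
        nxt, _ = recovery_step(treated, pre, [("J", 0, 1)], cfg)
        # J01 pre value 0.2 -> box is 0.2 +- 0.5*max(0.2, 0.1)
        assert 0.2 - 0.1 - 1e-12 <= nxt.j[0, 1] <= 0.2 + 0.1 + 1e-12


class TestRunRecovery:
    def test_zero_treatment_already_saturated(self, bilateral):
        spec = TreatmentSpec.node(5, 0.0)
        trace = run_recovery(
            apply_treatment(bilateral, spec), bilateral, spec
        )
        assert trace.n_iters == 0
        assert trace.saturated_at == 0
        assert trace.final == bilateral

    def test_empty_neighbor_set_is_noop(self):
        p = star(w=0.05)
        spec = TreatmentSpec.node(0, 0.5)
        treated = apply_treatment(p, spec)
        with pytest.warns(UserWarning, match="empty"):
            trace = run_recovery(treated, p, spec)
        assert trace.n_iters == 0
        assert trace.final == treated

    def test_degeneracy_functional_recovery_parameter_divergence(
        self, bilateral
    ):
        # one node's H perturbed: restoration more than halves the
        # functional distance while the J parameters move away from pre
        spec = TreatmentSpec.node(13, 0.5)
        treated = apply_treatment(bilateral, spec)
        sup = default_support(bilateral)
        trace = run_recovery(treated, bilateral, spec, support=sup)
        assert trace.saturated
        assert trace.d_curve[-1] < 0.5 * trace.d_curve[0]
        assert trace.rmsd_curve[-1] > trace.rmsd_curve[0]
        assert trace.rmsd_curve[0] == 0.0  # H-only treatment

    def test_curve_lengths_consistent(self, bilateral):
        spec = TreatmentSpec.node(13, 0.5)
        trace = run_recovery(
            apply_treatment(bilateral, spec), bilateral, spec
        )
        assert (
            len(trace.params_per_iter)
            == trace.d_curve.size
            == trace.rmsd_curve.size
        )


class TestStabilize:
    def test_saturated_trace_promotes_final(self, bilateral):
        spec = TreatmentSpec.node(13, 0.5)
        trace = run_recovery(
            apply_treatment(bilateral, spec), bilateral, spec
        )
        assert stabilize(trace) == trace.final

    def test_unsaturated_trace_refused(self):
        p = random_system(4, seed=8, j_scale=0.8)
        spec = TreatmentSpec.node(0, 1.0)
        cfg = RecoveryConfig(max_iters=1)
        trace = run_recovery(apply_treatment(p, spec), p, spec, cfg)
        assert not trace.saturated
        with pytest.raises(ValueError, match="not saturated"):
            stabilize(trace)

    def test_second_treatment_references_first_stabilized(self):
        from restormem import partial_kl

        p = random_system(4, seed=21, j_scale=0.8)
        spec1 = TreatmentSpec.node(0, 0.4)
        tr1 = run_recovery(apply_treatment(p, spec1), p, spec1)
        stab = stabilize(tr1)
        spec2 = TreatmentSpec.node(1, -0.3)
        treated2 = apply_treatment(stab, spec2)
        sup2 = default_support(stab)
        tr2 = run_recovery(treated2, stab, spec2, support=sup2)
        assert tr2.pre == stab
        assert tr2.d_curve[0] == pytest.approx(
            partial_kl(stab, treated2, sup2)
        )


class TestNoise:
    @staticmethod
    def _final_d(sd, seed):
        p = random_system(4, seed=2, j_scale=0.8)
        spec = TreatmentSpec.node(0, 0.5)
        cfg = RecoveryConfig(noise_sd=sd, seed=seed, max_iters=60)
        trace = run_recovery(apply_treatment(p, spec), p, spec, cfg)
        return trace.d_curve[-1]

    def test_fixed_seed_reproducible(self):
        assert self._final_d(0.02, 7) == self._final_d(0.02, 7)

    def test_spread_grows_with_noise_level(self):
        spreads = []
        for sd in (0.004, 0.02, 0.1):
            finals = [self._final_d(sd, s) for s in range(10)]
            spreads.append(np.std(finals))
        assert spreads[0] < spreads[1] < spreads[2]
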