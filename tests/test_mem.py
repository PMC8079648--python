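"""Exact enumeration of the pairwise MEM: energies, probabilities, moments."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from restormem import (
    State,
    SystemParams,
    energy,
    expectations,
    read_params,
    state_table,
    write_params,
)
from restormem.mem import energies

from conftest import brute_energies


class TestSystemParams:
    def test_rejects_asymmetric_j(self):
        with pytest.raises(ValueError, match="symmetric"):
            SystemParams(h=[0, 0], j=[[0, 1], [0.5, 0]])

    def test_rejects_shape_mismatch(self):
        with pytest.raises(ValueError, match="match"):
            SystemParams(h=[0, 0, 0], j=np.zeros((2, 2)))

    def test_diagonal_zeroed(self):
        p = SystemParams(h=[0, 0], j=[[5.0, 1.0], [1.0, 5.0]])
        assert p.j[0, 0] == 0.0 and p.j[1, 1] == 0.0


class TestStateLabels:
    def test_all_inactive_is_one_all_active_is_2n(self):
        assert State((0,) * 15).label == 1
        assert State((1,) * 15).label == 2**15  # 32768

    @given(st.integers(1, 2**6))
    def test_label_roundtrip(self, label):
        assert State.from_label(label, 6).label == label

    def test_rejects_nonbinary(self):
        with pytest.raises(ValueError):
            State((0, 2))


class TestEnergy:
    @pytest.mark.parametrize(
        "h,j12,sigma,expected",
        [
            ([0.3, -0.1], 0.7, (0, 0), 0.0),       # all terms vanish
            ([0.3, -0.1], 0.0, (1, 0), -0.3),      # single-site term
            ([0.0, 0.0], 1.0, (1, 1), -1.0),       # pair term only
            ([0.2, 0.4], 0.5, (1, 1), -1.1),       # both kinds of term
        ],
    )
    def test_known_values(self, h, j12, sigma, expected):
        p = SystemParams(h=h, j=[[0, j12], [j12, 0]])
        assert energy(p, State(sigma)) == pytest.approx(expected)

    def test_dimension_mismatch_names_sizes(self):
        p = SystemParams(h=[0, 0], j=np.zeros((2, 2)))
        with pytest.raises(ValueError, match="3.*2"):
            energy(p, State((0, 1, 1)))

    def test_matches_per_state_loop_oracle(self):
        rng = np.random.default_rng(42)
        for n in (2, 4, 6, 8):
            h = rng.normal(size=n)
            j = rng.normal(size=(n, n))
            j = np.triu(j, 1)
            p = SystemParams(h=h, j=j + j.T)
            np.testing.assert_allclose(
                energies(p), brute_energies(p), rtol=0, atol=1e-12
            )


class TestStateTable:
    def test_uniform_at_zero_parameters(self):
        p = SystemParams(h=np.zeros(3), j=np.zeros((3, 3)))
        tbl = state_table(p)
        np.testing.assert_allclose(tbl.probabilities, 1 / 8, atol=1e-15)

    def test_coupled_pair_probability(self, two_region_coupled):
        # four states: only (1,1) has energy -1
        tbl = state_table(two_region_coupled)
        assert tbl.probabilities[3] == pytest.approx(
            np.e / (3 + np.e), abs=1e-12
        )

    def test_probabilities_normalized(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            n = int(rng.integers(2, 7))
            h = rng.normal(size=n) * 2
            j = np.triu(rng.normal(size=(n, n)), 1)
            tbl = state_table(SystemParams(h=h, j=j + j.T))
            assert abs(tbl.probabilities.sum() - 1.0) < 1e-12
            assert (tbl.probabilities > 0).all()

    def test_extreme_parameters_stay_finite(self):
        p = SystemParams(h=[300.0, -300.0], j=np.zeros((2, 2)))
        tbl = state_table(p)
        assert np.isfinite(tbl.probabilities).all()
        assert tbl.probabilities.sum() == pytest.approx(1.0)

    def test_enumeration_cap(self):
        p = SystemParams(h=np.zeros(5), j=np.zeros((5, 5)))
        with pytest.raises(ValueError, match="cap"):
            state_table(p, cap=4)


class TestExpectations:
    def test_independent_uniform(self):
        p = SystemParams(h=np.zeros(3), j=np.zeros((3, 3)))
        act, coact = expectations(p)
        np.testing.assert_allclose(act, 0.5, atol=1e-14)
        off = coact[~np.eye(3, dtype=bool)]
        np.testing.assert_allclose(off, 0.25, atol=1e-14)
        np.testing.assert_allclose(np.diag(coact), act, atol=0)

    def test_coupled_pair_coactivation(self, two_region_coupled):
        _, coact = expectations(two_region_coupled)
        assert coact[0, 1] == pytest.approx(np.e / (3 + np.e), abs=1e-12)

    def test_strong_field_saturates(self):
        p = SystemParams(h=[50.0, 0.0], j=np.zeros((2, 2)))
        act, _ = expectations(p)
        assert act[0] == pytest.approx(1.0, abs=1e-12)

    def test_permuting_regions_permutes_expectations(self):
        rng = np.random.default_rng(11)
        n = 5
        h = rng.normal(size=n)
        j = np.triu(rng.normal(size=(n, n)), 1)
        j = j + j.T
        perm = rng.permutation(n)
        a1, c1 = expectations(SystemParams(h=h, j=j))
        a2, c2 = expectations(
            SystemParams(h=h[perm], j=j[np.ix_(perm, perm)])
        )
        np.testing.assert_allclose(a2, a1[perm], atol=1e-12)
        np.testing.assert_allclose(c2, c1[np.ix_(perm, perm)], atol=1e-12)


class TestParamsIO:
    def test_csv_roundtrip(self, tmp_path, bilateral):
        path = tmp_path / "p.csv"
        write_params(bilateral, str(path))
        back = read_params(str(path))
        np.testing.assert_array_equal(back.h, bilateral.h)
        np.testing.assert_array_equal(back.j, bilateral.j)
        assert back.region_labels == bilateral.region_labels

    def test_json_roundtrip(self, tmp_path, two_region_coupled):
        path = tmp_path / "p.json"
        write_params(two_region_coupled, str(path))
        back = read_params(str(path))
        np.testing.assert_array_equal(back.j, two_region_coupled.j)

    def test_mild_asymmetry_symmetrized_with_warning(self, tmp_path):
        import pandas as pd

        mat = np.array([[0.1, 0.2], [0.2 + 5e-8, -0.1]])
        path = tmp_path / "a.csv"
        pd.DataFrame(mat, index=["a", "b"], columns=["a", "b"]).to_csv(path)
        with pytest.warns(UserWarning, match="symmetrizing"):
            p = read_params(str(path))
        assert p.j[0, 1] == pytest.approx(0.2 + 2.5e-8)
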