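"""Spring selection, binding-leverage scoring, and the λ matrix."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import leverage_coupling as lc
from leverage_coupling.docking import ProbeLocation

from conftest import make_structure


def loc(probe, residues, sim_index=0, L=None):
    pl = ProbeLocation(
        probe_coords=np.asarray(probe, dtype=float).reshape(-1, 3),
        residues=frozenset(residues),
        sim_index=sim_index,
        final_energy=0.0,
    )
    if L is not None:
        pl.mode_leverages = np.asarray(L, dtype=float)
    return pl


def dense_sampling_springs(structure, location, pass_radius, n_samples=1000):
    """Oracle: sample points densely along each segment and test sphere
    membership around every probe atom."""
    members = sorted(location.residues)
    probe = location.probe_coords
    t = np.linspace(0.0, 1.0, n_samples)
    pairs = []
    for ai, i in enumerate(members):
        for j in members[ai + 1 :]:
            seg = structure.coords[i] + t[:, None] * (
                structure.coords[j] - structure.coords[i]
            )
            d = np.linalg.norm(seg[:, None, :] - probe[None, :, :], axis=-1)
            if (d <= pass_radius).any():
                pairs.append((i, j))
    return pairs


class TestSelectSprings:
    def test_midpoint_probe_selects_pair(self):
        structure = make_structure([[0, 0, 0], [8, 0, 0]])
        l = loc([[4.0, 0, 0]], {0, 1})
        assert lc.select_springs(structure, l) == [(0, 1)]

    def test_distant_probe_selects_nothing(self):
        structure = make_structure([[0, 0, 0], [8, 0, 0]])
        l = loc([[4.0, 5.0, 0]], {0, 1})
        assert lc.select_springs(structure, l, lc.LeverageParams(pass_radius=2.0)) == []

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_dense_sampling_oracle(self, seed):
        rng = np.random.default_rng(seed)
        structure = make_structure(rng.uniform(-10, 10, (12, 3)))
        l = loc(rng.uniform(-10, 10, (3, 3)), set(range(12)))
        params = lc.LeverageParams(pass_radius=2.0)
        assert set(lc.select_springs(structure, l, params)) == set(
            dense_sampling_springs(structure, l, 2.0)
        )


class TestProbeBindingLeverage:
    def test_rigid_translation_zero(self, chain20):
        springs = [(0, 5), (3, 9), (2, 17)]
        v = np.tile([0.3, -1.0, 0.7], (chain20.m, 1))
        assert lc.probe_binding_leverage(chain20, springs, v) == 0.0

    def test_hand_calculation(self):
        structure = make_structure([[0, 0, 0], [2, 0, 0]])
        v = np.array([[0.0, 0, 0], [1.0, 0, 0]])
        L = lc.probe_binding_leverage(structure, [(0, 1)], v)
        assert L == pytest.approx(0.5)

    def test_infinitesimal_rotation_zero(self, chain20):
        omega = np.array([0.4, -0.2, 1.0])
        v = np.cross(omega, chain20.coords - chain20.coords.mean(axis=0))
        springs = [(i, j) for i in range(0, 20, 3) for j in range(i + 1, 20, 5)]
        assert lc.probe_binding_leverage(chain20, springs, v) < 1e-12

    def test_sign_flip_invariant(self, chain20):
        rng = np.random.default_rng(4)
        v = rng.normal(size=(chain20.m, 3))
        springs = [(0, 4), (7, 12)]
        a = lc.probe_binding_leverage(chain20, springs, v)
        b = lc.probe_binding_leverage(chain20, springs, -v)
        assert a == pytest.approx(b) and a > 0

    def test_spring_constant_scales_linearly(self, chain20):
        rng = np.random.default_rng(4)
        v = rng.normal(size=(chain20.m, 3))
        springs = [(0, 4)]
        a = lc.probe_binding_leverage(chain20, springs, v, lc.LeverageParams(k=1.0))
        b = lc.probe_binding_leverage(chain20, springs, v, lc.LeverageParams(k=2.5))
        assert b == pytest.approx(2.5 * a)


class TestResidueLeverageMatrix:
    def test_direct_average(self):
        locs = [
            loc([[0, 0, 0]], {1, 2}, 0, L=[2.0]),
            loc([[0, 0, 0]], {2, 3}, 1, L=[4.0]),
        ]
        lam = lc.residue_leverage_matrix(locs, m=5, n_modes=1)
        np.testing.assert_allclose(lam.lam[:, 0], [0, 2, 3, 4, 0])
        np.testing.assert_allclose(lam.coverage, [0, 1, 2, 1, 0])

    def test_single_location_identity(self):
        locs = [loc([[0, 0, 0]], {0, 2}, 0, L=[1.5, 0.5])]
        lam = lc.residue_leverage_matrix(locs, m=3, n_modes=2)
        np.testing.assert_allclose(lam.lam[0], [1.5, 0.5])
        np.testing.assert_allclose(lam.lam[1], [0.0, 0.0])

    def test_empty_list_errors(self):
        with pytest.raises(ValueError, match="no probe locations"):
            lc.residue_leverage_matrix([], m=3, n_modes=1)

    def test_unscored_location_errors(self):
        with pytest.raises(ValueError, match="score_locations"):
            lc.residue_leverage_matrix([loc([[0, 0, 0]], {0})], m=1, n_modes=1)


def test_total_binding_leverage_is_row_sum():
    locs = [loc([[0, 0, 0]], {0, 1}, 0, L=[1.0, 2.0])]
    lam = lc.residue_leverage_matrix(locs, m=3, n_modes=2)
    np.testing.assert_allclose(lc.total_binding_leverage(lam), [3.0, 3.0, 0.0])
    single = lc.residue_leverage_matrix(
        [loc([[0, 0, 0]], {0}, 0, L=[2.5])], m=2, n_modes=1
    )
    np.testing.assert_allclose(
        lc.total_binding_leverage(single), single.lam[:, 0]
    )


class TestProfileSimilarity:
    def _lam(self, cols):
        lam = np.array(cols, dtype=float).T
        return lc.LeverageMatrix(
            lam=lam, coverage=np.ones(lam.shape[0]), mode_ids=list(range(lam.shape[1]))
        )

    def test_proportional_columns_give_one(self):
        sim = lc.profile_similarity(self._lam([[1, 2, 3], [2, 4, 6]]))
        np.testing.assert_allclose(sim.normalized, 1.0)

    def test_disjoint_support_gives_zero(self):
        sim = lc.profile_similarity(self._lam([[1, 0, 2], [0, 3, 0]]))
        assert sim.normalized[0, 1] == 0.0

    def test_hand_calculation(self):
        sim = lc.profile_similarity(self._lam([[1, 2, 0], [2, 1, 0]]))
        assert sim.Lambda[0, 1] == pytest.approx(4.0)
        assert sim.normalized[0, 1] == pytest.approx(0.8)

    def test_zero_profile_convention(self):
        sim = lc.profile_similarity(self._lam([[0, 0], [1, 1]]))
        assert sim.normalized[0, 0] == 0.0 and sim.normalized[0, 1] == 0.0
        assert sim.normalized[1, 1] == pytest.approx(1.0)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(
        st.lists(
            st.lists(st.floats(0, 100), min_size=3, max_size=3),
            min_size=4,
            max_size=8,
        )
    )
    def test_bounds_and_symmetry(self, rows):
        lam = lc.LeverageMatrix(
            lam=np.array(rows), coverage=np.ones(len(rows)), mode_ids=[0, 1, 2]
        )
        sim = lc.profile_similarity(lam)
        assert np.all(sim.normalized >= 0) and np.all(sim.normalized <= 1 + 1e-12)
        np.testing.assert_allclose(sim.normalized, sim.normalized.T, atol=1e-12)
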