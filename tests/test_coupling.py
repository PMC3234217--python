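"""Site leverage vectors and the D/C coupling matrices."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import leverage_coupling as lc
from leverage_coupling import Site
from leverage_coupling.coupling import SiteLeverageVector


def lam_matrix(rows):
    rows = np.array(rows, dtype=float)
    return lc.LeverageMatrix(
        lam=rows, coverage=np.ones(len(rows)), mode_ids=list(range(rows.shape[1]))
    )


class TestSiteLeverageVector:
    def test_singleton_is_that_row(self):
        lam = lam_matrix([[1, 2], [3, 4]])
        v = lc.site_leverage_vector(lam, Site("p", frozenset({1})))
        np.testing.assert_allclose(v.values, [3, 4])

    def test_uniform_rows_give_common_row(self):
        lam = lam_matrix([[1, 2], [1, 2], [9, 9]])
        v = lc.site_leverage_vector(lam, Site("p", frozenset({0, 1})))
        np.testing.assert_allclose(v.values, [1, 2])

    def test_hand_average(self):
        lam = lam_matrix([[1, 3], [3, 5]])
        v = lc.site_leverage_vector(lam, Site("p", frozenset({0, 1})))
        np.testing.assert_allclose(v.values, [2, 4])

    def test_out_of_range_member_errors(self):
        lam = lam_matrix([[1, 2]])
        with pytest.raises(ValueError, match="outside"):
            lc.site_leverage_vector(lam, Site("p", frozenset({5})))


class TestLeverageCoupling:
    def test_orthogonal_leverage_uncoupled(self):
        p = SiteLeverageVector("p", np.array([1.0, 0.0]))
        q = SiteLeverageVector("q", np.array([0.0, 1.0]))
        assert lc.leverage_coupling(p, q) == 0.0

    def test_hand_dot_product(self):
        p = SiteLeverageVector("p", np.array([1.0, 2.0]))
        q = SiteLeverageVector("q", np.array([3.0, 4.0]))
        assert lc.leverage_coupling(p, q) == pytest.approx(11.0)

    def test_symmetry_on_random_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            p = SiteLeverageVector("p", rng.uniform(0, 5, 6))
            q = SiteLeverageVector("q", rng.uniform(0, 5, 6))
            assert lc.leverage_coupling(p, q) == lc.leverage_coupling(q, p)

    def test_length_mismatch_errors(self):
        p = SiteLeverageVector("p", np.ones(2))
        q = SiteLeverageVector("q", np.ones(3))
        with pytest.raises(ValueError, match="mismatch"):
            lc.leverage_coupling(p, q)


class TestNormalizedCoupling:
    def test_self_coupling_is_one(self):
        D = np.array([[4.0, 2.0], [2.0, 9.0]])
        C = lc.normalized_coupling(D)
        np.testing.assert_allclose(np.diag(C), 1.0)

    def test_proportional_vectors_give_one(self):
        v = np.array([1.0, 2.0, 3.0])
        vecs = np.stack([v, 2 * v])
        C = lc.normalized_coupling(vecs @ vecs.T)
        np.testing.assert_allclose(C, 1.0)

    def test_hand_cosine(self):
        vecs = np.array([[1.0, 0.0], [1.0, 1.0]])
        C = lc.normalized_coupling(vecs @ vecs.T)
        assert C[0, 1] == pytest.approx(1 / np.sqrt(2))

    def test_zero_site_convention(self):
        D = np.array([[0.0, 0.0], [0.0, 4.0]])
        C = lc.normalized_coupling(D)
        assert C[0, 0] == 0.0 and C[0, 1] == 0.0 and C[1, 1] == 1.0

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(
        st.lists(
            st.lists(st.floats(0, 50), min_size=4, max_size=4),
            min_size=2,
            max_size=6,
        )
    )
    def test_range_bound_for_nonnegative_leverage(self, vec_rows):
        vecs = np.array(vec_rows)
        C = lc.normalized_coupling(vecs @ vecs.T)
        assert np.all(C >= 0.0) and np.all(C <= 1.0)
        np.testing.assert_allclose(C, C.T, atol=1e-12)


class TestSiteResidueCoupling:
    def test_zero_row_residue_uncoupled(self):
        lam = lam_matrix([[1, 2], [0, 0], [2, 1]])
        d = lc.site_residue_coupling(lam, Site("p", frozenset({0})))
        assert d[1] == 0.0

    def test_singleton_self_product(self):
        lam = lam_matrix([[1, 2], [3, 4]])
        d = lc.site_residue_coupling(lam, Site("p", frozenset({1})))
        assert d[1] == pytest.approx(np.sum(lam.lam[1] ** 2))

    def test_consistent_with_pairwise_coupling(self):
        rng = np.random.default_rng(8)
        lam = lam_matrix(rng.uniform(0, 3, (15, 4)))
        site = Site("p", frozenset({2, 5, 9}))
        d = lc.site_residue_coupling(lam, site)
        ell = lc.site_leverage_vector(lam, site)
        for i in range(15):
            singleton = lc.site_leverage_vector(lam, Site("i", frozenset({i})))
            assert d[i] == pytest.approx(lc.leverage_coupling(ell, singleton))


class TestBackgroundCoupling:
    def test_uniform_nonsite_rows(self):
        r = np.array([1.0, 2.0])
        lam = lam_matrix([r, r, r, [9, 9]])
        bg = lc.background_coupling(lam, [Site("p", frozenset({3}))])
        assert bg == pytest.approx(float(r @ r))

    def test_all_zero_rows(self):
        lam = lam_matrix([[0, 0], [0, 0], [1, 1]])
        assert lc.background_coupling(lam, [Site("p", frozenset({2}))]) == 0.0

    def test_no_nonsite_residue_errors(self):
        lam = lam_matrix([[1, 1]])
        with pytest.raises(ValueError, match="outside"):
            lc.background_coupling(lam, [Site("p", frozenset({0}))])

    def test_matches_brute_force_pair_loop(self):
        rng = np.random.default_rng(12)
        lam = lam_matrix(rng.uniform(0, 2, (50, 5)))
        sites = [Site("a", frozenset({0, 1, 2})), Site("b", frozenset({10, 11}))]
        non_site = [i for i in range(50) if i not in {0, 1, 2, 10, 11}]
        vals = [
            float(lam.lam[i] @ lam.lam[j])
            for ai, i in enumerate(non_site)
            for j in non_site[ai + 1 :]
        ]
        assert lc.background_coupling(lam, sites) == pytest.approx(
            np.mean(vals), abs=1e-12
        )


class TestSingleModeCoupling:
    def test_decomposition_sums_to_full_matrix(self):
        rng = np.random.default_rng(3)
        lam = lam_matrix(rng.uniform(0, 2, (20, 6)))
        sites = [
            Site("a", frozenset({0, 1})),
            Site("b", frozenset({5, 6, 7})),
            Site("c", frozenset({12})),
        ]
        cm = lc.coupling_matrix(lam, sites)
        total = sum(lc.single_mode_coupling(lam, sites, mu) for mu in range(6))
        np.testing.assert_allclose(total, cm.D, atol=1e-12)

    def test_zero_mode_gives_zero_matrix(self):
        lam = lam_matrix([[1, 0], [2, 0]])
        D1 = lc.single_mode_coupling(lam, [Site("a", frozenset({0, 1}))], 1)
        np.testing.assert_allclose(D1, 0.0)

    def test_rank_at_most_one(self):
        rng = np.random.default_rng(5)
        lam = lam_matrix(rng.uniform(0, 2, (20, 4)))
        sites = [Site(n, frozenset({3 * i, 3 * i + 1})) for i, n in enumerate("abcd")]
        for mu in range(4):
            Dm = lc.single_mode_coupling(lam, sites, mu)
            assert np.linalg.matrix_rank(Dm, tol=1e-10) <= 1

    def test_unknown_mode_errors(self):
        lam = lam_matrix([[1, 2]])
        with pytest.raises(ValueError, match="mode"):
            lc.single_mode_coupling(lam, [Site("a", frozenset({0}))], 7)


def test_adding_a_mode_never_decreases_coupling():
    rng = np.random.default_rng(9)
    lam_full = rng.uniform(0, 2, (20, 5))
    sites = [Site("a", frozenset({0, 1})), Site("b", frozenset({8, 9}))]
    prev = np.zeros((2, 2))
    for n in range(1, 6):
        lam = lc.LeverageMatrix(
            lam=lam_full[:, :n], coverage=np.ones(20), mode_ids=list(range(n))
        )
        D = lc.coupling_matrix(lam, sites, include_background=False).D
        assert np.all(D >= prev - 1e-12)
        prev = D
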