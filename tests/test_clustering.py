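"""Partial distances, PDSFCM behavior, FS selection and memberships."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from seasonalcgm.clustering import (
    EmptyOverlapError,
    assign_crisp,
    calibrate_eta,
    fs_index,
    partial_distance,
    pdsfcm,
    possibilistic_membership,
    segment_membership,
    select_c,
)


class TestPartialDistance:
    def test_euclidean_case(self):
        assert partial_distance(np.array([0.0, 3.0]), np.array([4.0, 0.0])) == 5.0

    def test_hand_blank_case(self):
        a = np.array([1.0, 2.0, np.nan, 4.0])
        b = np.array([1.0, 3.0, 5.0, np.nan])
        assert partial_distance(a, b) == pytest.approx(np.sqrt(2.0), abs=1e-12)

    def test_identity(self):
        a = np.array([3.0, 1.0, 4.0])
        assert partial_distance(a, a) == 0.0

    def test_empty_overlap_raises(self):
        with pytest.raises(EmptyOverlapError):
            partial_distance(np.array([1.0, np.nan]), np.array([np.nan, 2.0]))

    @given(hnp.arrays(float, 6, elements=st.floats(-100, 100)),
           hnp.arrays(float, 6, elements=st.floats(-100, 100)))
    @settings(max_examples=100, deadline=None)
    def test_symmetric_nonnegative_euclidean_when_complete(self, a, b):
        d = partial_distance(a, b)
        assert d == partial_distance(b, a)
        assert d >= 0
        assert d == pytest.approx(float(np.linalg.norm(a - b)), abs=1e-9)

    def test_zero_iff_jointly_observed_agree(self):
        a = np.array([1.0, np.nan, 3.0])
        b = np.array([1.0, 7.0, np.nan])
        assert partial_distance(a, b) == 0.0


def reference_fcm(X, c, m, U0, tol=1e-5, max_iter=200):
    """Textbook complete-data fuzzy c-means, same init/stopping convention."""
    U = U0.copy()
    for _ in range(max_iter):
        W = U ** m
        V = (W @ X) / W.sum(axis=1)[:, None]
        d2 = ((X[None, :, :] - V[:, None, :]) ** 2).sum(axis=2)
        Un = (d2 ** (-1 / (m - 1))) / (d2 ** (-1 / (m - 1))).sum(axis=0)
        delta = np.abs(Un - U).max()
        U = Un
        if delta < tol:
            break
    return U, V


class TestPdsfcm:
    def test_matches_reference_fcm_on_complete_data(self):
        rng = np.random.default_rng(3)
        X = np.concatenate([rng.normal(0, 1, (15, 8)), rng.normal(6, 1, (15, 8))])
        U0 = np.random.default_rng(0).dirichlet(np.ones(2), size=30).T
        U_ref, V_ref = reference_fcm(X, 2, 2.0, U0)
        fit = pdsfcm(X, 2, m=2.0, restarts=1, seed=0)
        # same Dirichlet(1) init from the same seed drives both paths
        np.testing.assert_allclose(fit.U, U_ref, atol=1e-8)
        np.testing.assert_allclose(fit.V, V_ref, atol=1e-8)

    def test_objective_monotone_and_row_stochastic(self, planted3):
        part, _ = planted3
        fit = pdsfcm(part, 3, restarts=2, seed=1)
        hist = fit.jm_history
        assert all(b <= a + 1e-9 * max(1, abs(a)) for a, b in zip(hist, hist[1:]))
        np.testing.assert_allclose(fit.U.sum(axis=0), 1.0, atol=1e-9)
        assert np.all(fit.U >= 0) and np.all(fit.U <= 1)

    def test_separated_identical_rows_fixed_point(self):
        row_a = np.full(6, 10.0)
        row_b = np.full(6, 200.0)
        X = np.array([row_a, row_a, row_a, row_b, row_b, row_b])
        fit = pdsfcm(X, 2, restarts=3, seed=0)
        protos = fit.V[np.argsort(fit.V[:, 0])]
        np.testing.assert_allclose(protos[0], row_a, atol=1e-6)
        np.testing.assert_allclose(protos[1], row_b, atol=1e-6)
        assert np.all((fit.U > 0.999) | (fit.U < 0.001))

    def test_c_larger_than_n_is_error(self):
        with pytest.raises(ValueError):
            pdsfcm(np.zeros((3, 4)), 5)

    def test_unobserved_column_is_error(self):
        X = np.array([[1.0, np.nan], [2.0, np.nan]])
        with pytest.raises(ValueError, match="never observed"):
            pdsfcm(X, 2)


class TestFsIndexAndSelection:
    def test_fs_minimized_at_planted_c(self, planted3):
        part, _ = planted3
        fs = {}
        for c in (2, 3, 4):
            fit = pdsfcm(part, c, restarts=3, seed=0)
            fs[c] = fs_index(fit, part)
        assert fs[3] < fs[2] and fs[3] < fs[4]

    def test_fs_decreases_with_separation(self):
        fs_vals = []
        for sep in (20.0, 60.0, 120.0):
            rng = np.random.default_rng(5)
            X = np.concatenate([
                100 + rng.normal(0, 3, (12, 10)),
                100 + sep + rng.normal(0, 3, (12, 10)),
            ])
            fit = pdsfcm(X, 2, restarts=2, seed=0)
            fs_vals.append(fs_index(fit, X))
        assert fs_vals[0] > fs_vals[1] > fs_vals[2]

    def test_select_c_recovers_planted_templates(self, planted3):
        from sklearn.metrics import adjusted_rand_score

        part, labels = planted3
        fit = select_c(part, c_range=range(2, 7), seed=0)
        assert fit.c == 3
        ari = adjusted_rand_score(labels, assign_crisp(fit))
        assert ari > 0.9

    def test_small_n_single_model_fallback(self):
        X = 100 + np.random.default_rng(0).normal(0, 5, (4, 6))
        fit = select_c(X, n_min=10)
        assert fit.c == 1
        np.testing.assert_allclose(fit.U, 1.0)
        np.testing.assert_allclose(fit.V[0], X.mean(axis=0), atol=1e-9)

    def test_singleton_range_returns_that_fit(self, planted3):
        part, _ = planted3
        fit = select_c(part, c_range=[2], seed=0)
        assert fit.c == 2


class TestSegmentMembership:
    def test_hand_two_prototypes(self):
        g = np.zeros(4)
        protos = [np.full(4, 1.0) / 2, np.full(4, 1.0)]  # distances 1 and 2
        u = segment_membership(g, protos, m=2.0)
        np.testing.assert_allclose(u, [0.8, 0.2], atol=1e-12)

    def test_zero_distance_one_hot(self):
        g = np.array([5.0, 6.0])
        protos = [np.array([1.0, 1.0]), np.array([2.0, 2.0]), g.copy()]
        u = segment_membership(g, protos)
        np.testing.assert_allclose(u, [0.0, 0.0, 1.0])

    def test_equidistant_uniform(self):
        g = np.zeros(3)
        protos = [np.full(3, 2.0), np.full(3, -2.0)]
        np.testing.assert_allclose(segment_membership(g, protos), [0.5, 0.5])


class TestPossibilistic:
    def test_zero_distance_gives_one(self):
        g = np.array([1.0, 2.0])
        assert possibilistic_membership(g, g, eta=0.5) == 1.0

    def test_half_at_unit_eta_d2(self):
        g = np.array([0.0, 0.0])
        proto = np.array([1.0, 1.0])  # d2 = 2
        assert possibilistic_membership(g, proto, eta=0.5) == pytest.approx(0.5)

    def test_vanishes_far_away(self):
        g = np.array([0.0])
        proto = np.array([500.0])
        assert possibilistic_membership(g, proto, eta=1.0) < 0.01


class TestCalibrateEta:
    def test_constant_distance_construction(self):
        # every window sits at squared distance 4 from the prototype
        X = np.full((12, 6), 100.0 + np.sqrt(2.0))
        V = np.full((1, 6), 100.0)
        from seasonalcgm.clustering import ClusterSet

        cs = ClusterSet(c=1, m=2.0, V=V, U=np.ones((1, 12)), Jm=0.0, L=6)
        eta = calibrate_eta(cs, X, window=2)
        assert eta == pytest.approx(0.25)

    def test_degenerate_uses_ceiling(self):
        X = np.full((12, 6), 100.0)
        from seasonalcgm.clustering import ClusterSet

        cs = ClusterSet(c=1, m=2.0, V=np.full((1, 6), 100.0),
                        U=np.ones((1, 12)), Jm=0.0, L=6)
        assert calibrate_eta(cs, X, window=2) == pytest.approx(1e6)

    def test_scale_covariance(self):
        rng = np.random.default_rng(2)
        base = rng.normal(0, 1, (15, 8))
        from seasonalcgm.clustering import ClusterSet

        def eta_for(scale):
            X = 100 + scale * base
            cs = ClusterSet(c=1, m=2.0, V=np.full((1, 8), 100.0),
                            U=np.ones((1, 15)), Jm=0.0, L=8)
            return calibrate_eta(cs, X, window=3)

        assert eta_for(2.0) == pytest.approx(eta_for(1.0) / 4.0, rel=1e-9)


class TestAssignCrisp:
    def test_argmax_and_tie_rule(self):
        from seasonalcgm.clustering import ClusterSet

        U = np.array([[0.5, 0.2, 1 / 3], [0.5, 0.7, 1 / 3], [0.0, 0.1, 1 / 3]])
        cs = ClusterSet(c=3, m=2.0, V=np.zeros((3, 2)), U=U, Jm=0.0, L=2)
        np.testing.assert_array_equal(assign_crisp(cs), [0, 1, 0])
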