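import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import minimize
from scipy.stats import spearmanr

from oracles import atgp_oracle_indices
from ivimhsi.detect import (
    KernelSpec,
    atgp,
    cem,
    correlation_matrix,
    kcem,
    osp_projector,
    rbf_kernel,
    sam,
    select_training_samples,
)


class TestOspProjector:
    def test_axis_vector_projector(self):
        P = osp_projector(np.array([[1.0], [0.0]]))
        np.testing.assert_allclose(P, np.diag([0.0, 1.0]), atol=1e-12)

    def test_projector_identities(self, rng):
        U = rng.normal(size=(6, 2))
        P = osp_projector(U)
        np.testing.assert_allclose(P, P.T, atol=1e-10)
        np.testing.assert_allclose(P @ P, P, atol=1e-10)
        np.testing.assert_allclose(P @ U, 0, atol=1e-10)

    def test_matches_qr_complement_oracle(self, rng):
        U = rng.normal(size=(5, 2))
        Q, _ = np.linalg.qr(U)
        np.testing.assert_allclose(osp_projector(U), np.eye(5) - Q @ Q.T, atol=1e-10)

    def test_rank_deficient_rejected(self):
        U = np.array([[1.0, 2.0], [2.0, 4.0], [0.0, 0.0]])
        with pytest.raises(ValueError, match="rank"):
            osp_projector(U)


class TestAtgp:
    def test_brightest_pixel_is_first_target(self, rng):
        X = rng.normal(size=(30, 4))
        X[17] *= 50
        ts = atgp(X, n_targets=1)
        assert ts.indices[0] == 17

    def test_orthogonal_blocks_yield_one_target_each(self):
        cube = np.zeros((4, 2, 1, 2))
        cube[:2, :, 0, 0] = 5.0  # block A along e1
        cube[2:, :, 0, 1] = 3.0  # block B along e2
        ts = atgp(cube, n_targets=2)
        rows = ts.spatial_indices()[:, 0]
        assert rows[0] < 2 and rows[1] >= 2

    def test_matches_exhaustive_argmax_oracle(self, rng):
        for _ in range(20):
            X = rng.normal(size=(rng.integers(4, 12), rng.integers(2, 4)))
            k = int(min(3, X.shape[1]))
            ts = atgp(X, n_targets=k)
            assert ts.indices.tolist() == atgp_oracle_indices(X, k)

    def test_epsilon_stopping_discards_trigger(self, rng):
        X = rng.normal(size=(20, 3))
        ts = atgp(X, n_targets=10, epsilon=np.pi)  # any angle <= pi stops at once
        assert len(ts) == 1 and ts.stop_reason == "epsilon"

    def test_all_zero_cube_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            atgp(np.zeros((5, 3)), n_targets=1)

    def test_too_many_targets_rejected(self, rng):
        with pytest.raises(ValueError, match="exceeds"):
            atgp(rng.normal(size=(4, 2)), n_targets=5)


class TestSam:
    def test_identical_vectors_zero_angle(self):
        assert sam([1.0, 2.0, 3.0], [1, 2, 3]) == pytest.approx(0.0, abs=1e-7)

    def test_orthogonal_vectors(self):
        assert sam([1, 0], [0, 1]) == pytest.approx(np.pi / 2)

    def test_forty_five_degrees(self):
        assert sam([1, 0], [1, 1]) == pytest.approx(np.pi / 4)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            sam([0, 0], [1, 0])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        s=st.lists(st.floats(-10, 10), min_size=3, max_size=3),
        t=st.lists(st.floats(-10, 10), min_size=3, max_size=3),
        a=st.floats(min_value=1e-3, max_value=1e3),
    )
    def test_scale_invariant_and_symmetric(self, s, t, a):
        s, t = np.asarray(s), np.asarray(t)
        if np.linalg.norm(s) < 1e-6 or np.linalg.norm(t) < 1e-6:
            return
        assert sam(a * s, t) == pytest.approx(sam(s, t), abs=1e-6)
        assert sam(s, t) == pytest.approx(sam(t, s), abs=1e-9)


class TestSelectTrainingSamples:
    def test_two_clusters_recovered_between_angles(self, rng):
        base1 = np.array([1.0, 0.0, 0.0])
        base2 = np.array([0.0, 1.0, 0.0])
        X = np.vstack(
            [base1 * s for s in rng.uniform(1, 2, 10)]
            + [base2 * s for s in rng.uniform(1, 2, 10)]
        )
        ts = atgp(X, n_targets=2)
        sets = select_training_samples(X, ts, angle_threshold=0.3)
        got = [set(sel.tolist()) for sel, _ in sets]
        assert {frozenset(range(10)), frozenset(range(10, 20))} == {frozenset(g) for g in got}
        for sel, d in sets:
            np.testing.assert_allclose(d, X[sel].mean(axis=0))

    def test_pi_threshold_selects_every_pixel(self, rng):
        X = rng.normal(size=(12, 3))
        ts = atgp(X, n_targets=1)
        sets = select_training_samples(X, ts, angle_threshold=np.pi)
        assert len(sets[0][0]) == 12

    def test_tiny_threshold_gives_singleton_target_sets(self, rng):
        # a target always matches itself at angle 0, so a vanishing threshold
        # reduces each training set to the target pixel alone
        X = np.vstack([np.eye(3), [[1.0, 1.0, 1.0]]])
        ts = atgp(X, n_targets=2)
        sets = select_training_samples(X, ts, angle_threshold=1e-12)
        for k, (sel, d) in enumerate(sets):
            assert ts.indices[k] in sel
            np.testing.assert_allclose(d, X[sel].mean(axis=0))


class TestCorrelationMatrix:
    def test_single_pixel_outer_product(self):
        r = np.array([[1.0, 2.0]])
        np.testing.assert_allclose(correlation_matrix(r), np.outer(r[0], r[0]))

    def test_two_unit_pixels(self):
        X = np.eye(2)
        np.testing.assert_allclose(correlation_matrix(X), 0.5 * np.eye(2))

    def test_matches_loop_oracle(self, rng):
        X = rng.normal(size=(10, 4))
        R = sum(np.outer(x, x) for x in X) / 10
        np.testing.assert_allclose(correlation_matrix(X), R, atol=1e-12)


class TestCem:
    def test_unit_response_on_desired_signature(self, rng):
        X = rng.uniform(0.1, 1.0, size=(30, 5))
        d = X[11]
        out = cem(X, d)
        assert out[11] == pytest.approx(1.0, abs=1e-8)

    def test_matches_constrained_minimizer_oracle(self, rng):
        # independent route: numerically minimize w'Rw subject to w'd = 1
        X = rng.normal(size=(3, 2))
        d = rng.normal(size=2)
        ridge = 1e-9
        R = X.T @ X / 3 + ridge * np.eye(2)
        res = minimize(
            lambda w: w @ R @ w,
            x0=d / (d @ d),
            constraints={"type": "eq", "fun": lambda w: w @ d - 1.0},
            tol=1e-14,
        )
        w_impl = np.linalg.solve(R, d) / (d @ np.linalg.solve(R, d))
        np.testing.assert_allclose(w_impl, res.x, atol=1e-6)
        np.testing.assert_allclose(cem(X, d, ridge=ridge), X @ w_impl, atol=1e-8)

    def test_suppresses_orthogonal_background(self, rng):
        d = np.array([1.0, 0.0, 0.0])
        bg = np.column_stack([np.zeros(40), rng.normal(size=(40, 2))])
        X = np.vstack([bg, d])
        out = cem(X, d)
        assert out[-1] == pytest.approx(1.0, abs=1e-6)
        assert np.max(np.abs(out[:-1])) < 1e-3

    def test_singular_without_ridge_instructs_ridge(self):
        X = np.array([[1.0, 0.0], [2.0, 0.0]])
        with pytest.raises(np.linalg.LinAlgError, match="ridge"):
            cem(X, np.array([1.0, 0.0]), ridge=0)

    def test_invariant_to_joint_rescaling(self, rng):
        X = rng.uniform(0.1, 1.0, size=(20, 4))
        d = X[3]
        np.testing.assert_allclose(cem(X, d, ridge=0), cem(5 * X, 5 * d, ridge=0), atol=1e-8)


class TestRbfKernel:
    def test_self_similarity_is_one(self, rng):
        x = rng.normal(size=5)
        assert rbf_kernel(x, x, 2.0) == 1.0

    def test_characteristic_distance(self):
        sigma = 1.7
        x = np.zeros(2)
        y = np.array([sigma * np.sqrt(2.0), 0.0])
        assert rbf_kernel(x, y, sigma) == pytest.approx(np.exp(-1.0))

    def test_matches_loop_distance_oracle(self, rng):
        x, y = rng.normal(size=4), rng.normal(size=4)
        d2 = sum((a - b) ** 2 for a, b in zip(x, y))
        assert rbf_kernel(x, y, 0.9) == pytest.approx(np.exp(-d2 / (2 * 0.81)), rel=1e-12)

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValueError):
            rbf_kernel([0.0], [1.0], 0.0)


class TestKcem:
    def test_linear_kernel_equals_cem(self, rng):
        X = rng.uniform(0.1, 2.0, size=(60, 6))
        d = X[7]
        lin = kcem(X, d, kernel=KernelSpec("linear"))
        ref = cem(X, d)
        np.testing.assert_allclose(lin, ref, atol=1e-6)

    def test_unit_response_on_desired_signature(self, rng):
        X = rng.uniform(0.1, 2.0, size=(50, 4))
        d = X[5]
        out = kcem(X, d, kernel=KernelSpec("rbf", 1.0))
        assert out[5] == pytest.approx(1.0, abs=1e-6)

    def test_large_sigma_matches_first_order_feature_map_oracle(self, rng):
        # first-order expansion of the RBF kernel: k(x,y) = g(x)'g(y) + O(s^-4)
        # with explicit features g(x) = [1 - |x|^2/(2 s^2), x/s]; at large s
        # the kernel detector must track CEM built in that feature space
        M, N = 8, 200
        p1 = np.abs(np.sin(np.linspace(0, 3, M))) + 0.5
        p2 = np.abs(np.cos(np.linspace(0, 3, M))) + 0.5
        X = np.abs(rng.uniform(0.2, 1.5, (N, 2)) @ np.vstack([p1, p2]))
        d = X[3]
        from ivimhsi.detect import median_heuristic_sigma

        s = 50 * median_heuristic_sigma(X)
        rho = 1e-6

        def g(A):
            A = np.atleast_2d(A)
            return np.column_stack([1 - (A**2).sum(axis=1) / (2 * s**2), A / s])

        Y = g(X)
        R = Y.T @ Y / N + rho * np.eye(M + 1)
        w = np.linalg.solve(R, g(d).ravel())
        oracle = Y @ w / (g(d).ravel() @ w)

        wide = kcem(X, d, kernel=KernelSpec("rbf", s), ridge=rho)
        assert spearmanr(wide, oracle).statistic > 0.99

    def test_seeded_subsample_is_deterministic(self, rng):
        X = rng.uniform(0.1, 2.0, size=(300, 3))
        d = X[0]
        a = kcem(X, d, background_subsample=100, seed=5)
        b = kcem(X, d, background_subsample=100, seed=5)
        np.testing.assert_array_equal(a, b)
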