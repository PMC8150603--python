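"""Subspace alignment: MMD matrices, distances and the generalized eigenproblem."""

import numpy as np
import pytest

from siteadapt import (
    DomainPair,
    ShiftConfig,
    gen_domain_shift,
    mmd_distance,
    mmd_matrix_conditional,
    mmd_matrix_marginal,
    project,
    solve_projection,
)
from siteadapt.adaptation import ProjectionModel, centering_matrix


class TestMarginalMatrix:
    def test_block_values_2_2(self):
        M = mmd_matrix_marginal(2, 2)
        np.testing.assert_allclose(M[:2, :2], 0.25)
        np.testing.assert_allclose(M[2:, 2:], 0.25)
        np.testing.assert_allclose(M[:2, 2:], -0.25)

    def test_minimal_1_1(self):
        np.testing.assert_allclose(mmd_matrix_marginal(1, 1), [[1, -1], [-1, 1]])

    @pytest.mark.parametrize("ns,nt", [(3, 5), (10, 2), (7, 7)])
    def test_rows_sum_to_zero(self, ns, nt):
        M = mmd_matrix_marginal(ns, nt)
        np.testing.assert_allclose(M.sum(axis=1), 0.0, atol=1e-14)
        np.testing.assert_allclose(M, M.T)

    def test_nonpositive_counts_rejected(self):
        with pytest.raises(ValueError):
            mmd_matrix_marginal(0, 3)


class TestConditionalMatrix:
    def test_single_member_blocks(self):
        ys = np.array([1, 2, 2])
        yt = np.array([1, 2])
        M = mmd_matrix_conditional(ys, yt, 1)
        active = np.ix_([0, 3], [0, 3])
        np.testing.assert_allclose(M[active], [[1, -1], [-1, 1]])
        M_zeroed = M.copy()
        M_zeroed[active] = 0.0
        np.testing.assert_allclose(M_zeroed, 0.0)

    def test_class_rows_sum_to_zero(self, rng):
        ys = rng.integers(1, 3, size=12)
        ys[:2] = [1, 2]
        yt = rng.integers(1, 3, size=9)
        yt[:2] = [1, 2]
        for c in (1, 2):
            M = mmd_matrix_conditional(ys, yt, c)
            np.testing.assert_allclose(M.sum(axis=1), 0.0, atol=1e-14)

    def test_class_absent_from_target_gives_zero(self):
        M = mmd_matrix_conditional(np.array([1, 1, 2]), np.array([2, 2]), 1)
        np.testing.assert_allclose(M, 0.0)

    def test_class_absent_from_source_rejected(self):
        with pytest.raises(ValueError):
            mmd_matrix_conditional(np.array([1, 1]), np.array([2]), 2)


class TestMMDDistance:
    def test_identical_samples_zero(self, rng):
        Z = rng.standard_normal((3, 10))
        assert mmd_distance(Z, Z) == pytest.approx(0.0)

    def test_hand_computed_value(self):
        Zs = np.array([[0.0], [0.0]])
        Zt = np.array([[3.0], [4.0]])
        assert mmd_distance(Zs, Zt) == pytest.approx(25.0)

    def test_empty_domain_rejected(self):
        with pytest.raises(ValueError):
            mmd_distance(np.empty((2, 0)), np.ones((2, 3)))

    def test_mean_difference_equals_trace_form(self, rng):
        """The mean-difference MMD must equal tr(W'X M0 X'W) for any W."""
        for _ in range(100):
            d, k, ns, nt = 6, 3, 8, 11
            X = rng.standard_normal((d, ns + nt))
            W = rng.standard_normal((d, k))
            Zs, Zt = W.T @ X[:, :ns], W.T @ X[:, ns:]
            trace_form = np.trace(W.T @ X @ mmd_matrix_marginal(ns, nt) @ X.T @ W)
            assert mmd_distance(Zs, Zt) == pytest.approx(trace_form, abs=1e-8)


@pytest.fixture(scope="module")
def random_pair():
    rng = np.random.default_rng(0)
    Xs = rng.standard_normal((50, 100))
    Xt = rng.standard_normal((50, 100)) + 0.5
    ys = np.repeat([1, 2], 50)
    return DomainPair(Xs=Xs, ys=ys, Xt=Xt)


class TestSolveProjection:
    def test_eigen_residual_below_tolerance(self, random_pair):
        pair, k, lam = random_pair, 10, 1.0
        model = solve_projection(pair, k=k, lambda_reg=lam)
        X = np.hstack([pair.Xs, pair.Xt])
        Xc = X - X.mean(axis=1, keepdims=True)
        n = X.shape[1]
        A = Xc @ mmd_matrix_marginal(pair.ns, pair.nt) @ Xc.T + lam * np.eye(50)
        B = Xc @ centering_matrix(n) @ Xc.T
        residual = np.linalg.norm(A @ model.W - B @ model.W @ np.diag(model.eigenvalues))
        assert residual / np.linalg.norm(model.W) < 1e-6

    def test_constraint_satisfied(self, random_pair):
        model = solve_projection(random_pair, k=10)
        X = np.hstack([random_pair.Xs, random_pair.Xt])
        Xc = X - X.mean(axis=1, keepdims=True)
        G = model.W.T @ Xc @ centering_matrix(X.shape[1]) @ Xc.T @ model.W
        np.testing.assert_allclose(G, np.eye(10), atol=1e-6)

    def test_eigenvalues_ascending(self, random_pair):
        model = solve_projection(random_pair, k=10)
        assert np.all(np.diff(model.eigenvalues) >= -1e-12)

    def test_beats_random_orthonormal_projection(self, rng):
        src, tgt, _ = gen_domain_shift(ShiftConfig(n_source=60, n_target=60, dims=12, seed=5))
        pair = DomainPair(Xs=src.X.T, ys=src.labels, Xt=tgt.X.T)
        model = solve_projection(pair, k=4)
        X = np.hstack([pair.Xs, pair.Xt])
        Xc = X - X.mean(axis=1, keepdims=True)
        M0 = mmd_matrix_marginal(pair.ns, pair.nt)

        def objective(W):
            return np.trace(W.T @ Xc @ M0 @ Xc.T @ W)

        Q, _ = np.linalg.qr(rng.standard_normal((12, 4)))
        assert objective(model.W) <= objective(Q)

    def test_no_shift_projected_mmd_small(self):
        src, tgt, _ = gen_domain_shift(
            ShiftConfig(n_source=200, n_target=200, dims=6, rotation_deg=0, shift_mag=0, seed=2)
        )
        pair = DomainPair(Xs=src.X.T, ys=src.labels, Xt=tgt.X.T)
        model = solve_projection(pair, k=3)
        assert mmd_distance(project(pair.Xs, model), project(pair.Xt, model)) < 0.01

    def test_k_too_large_rejected(self, random_pair):
        with pytest.raises(ValueError):
            solve_projection(random_pair, k=51)


class TestProject:
    def test_identity_transform(self, rng):
        X = rng.standard_normal((4, 9))
        model = ProjectionModel(W=np.eye(4), eigenvalues=np.zeros(4), k=4,
                                lambda_reg=0.0, mean_=np.zeros(4))
        np.testing.assert_allclose(project(X, model), X)

    def test_zero_input(self):
        model = ProjectionModel(W=np.ones((3, 2)), eigenvalues=np.zeros(2), k=2,
                                lambda_reg=0.0, mean_=np.zeros(3))
        np.testing.assert_allclose(project(np.zeros((3, 5)), model), 0.0)

    def test_dimension_mismatch_rejected(self):
        model = ProjectionModel(W=np.ones((3, 2)), eigenvalues=np.zeros(2), k=2,
                                lambda_reg=0.0, mean_=np.zeros(3))
        with pytest.raises(ValueError):
            project(np.zeros((4, 5)), model)

    def test_model_save_load_round_trip(self, tmp_path, random_pair=None):
        rng = np.random.default_rng(1)
        model = ProjectionModel(W=rng.standard_normal((5, 2)), eigenvalues=np.array([0.1, 0.2]),
                                k=2, lambda_reg=1.0, mean_=rng.standard_normal(5))
        model.save(tmp_path / "m")
        back = ProjectionModel.load(tmp_path / "m")
        np.testing.assert_allclose(back.W, model.W)
        np.testing.assert_allclose(back.mean_, model.mean_)
        assert back.k == 2 and back.lambda_reg == 1.0
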