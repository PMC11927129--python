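import numpy as np
import pytest
import scipy.linalg

from gwablup import (
    MmeOperator,
    SnpBlup,
    TraitModel,
    ValidationError,
    build_prior,
    center_genotypes,
    pcg_solve,
    predict,
)
from gwablup.snpblup import block_preconditioner

from conftest import random_panel


def dense_mme(M, R, w, theta_blocks, eps):
    """Independent dense assembly of the three-block augmented system."""
    n, N = M.shape
    T = R.shape[0]
    Rinv = np.linalg.inv(R)
    X = np.tile(np.eye(T), (n, 1))                      # 1_n (x) I_T
    Re_inv = np.kron(np.diag(w), Rinv)                  # (W^-1 (x) R^-1)
    Z = np.kron(M, np.eye(T))
    theta_inv = scipy.linalg.block_diag(
        *[np.linalg.inv(b) for b in theta_blocks])
    A = np.zeros((T + n * T + N * T,) * 2)
    A[:T, :T] = X.T @ Re_inv @ X
    A[:T, T:T + n * T] = X.T @ Re_inv
    A[T:T + n * T, :T] = Re_inv @ X
    A[T:T + n * T, T:T + n * T] = Re_inv + np.eye(n * T) / eps
    A[T:T + n * T, T + n * T:] = -Z / eps
    A[T + n * T:, T:T + n * T] = -Z.T / eps
    A[T + n * T:, T + n * T:] = Z.T @ Z / eps + theta_inv
    return A, Re_inv, X


def dense_rhs(Re_inv, X, Y, N, T):
    yvec = Y.ravel()
    return np.concatenate(
        [X.T @ Re_inv @ yvec, Re_inv @ yvec, np.zeros(N * T)])


@pytest.fixture
def assembled(rng, tiny_instance):
    panel, phen, traits = tiny_instance
    cg = center_genotypes(panel)
    prior = build_prior("unweighted", traits, cg.scale_sum,
                        n_snps=cg.n_snps)
    eps = 0.01
    op = MmeOperator(cg.matrix, traits.R, phen.record_weight, prior, eps)
    A, Re_inv, X = dense_mme(cg.matrix, traits.R, phen.record_weight,
                             prior.blocks, eps)
    rhs = dense_rhs(Re_inv, X, phen.yd, cg.n_snps, traits.n_traits)
    return op, A, rhs, cg, phen, traits


class TestOperator:
    def test_matvec_matches_dense_assembly(self, rng, assembled):
        op, A, _, *_ = assembled
        for _ in range(5):
            v = rng.standard_normal(op.n_unknowns)
            np.testing.assert_allclose(op.matvec(v), A @ v, rtol=1e-9,
                                       atol=1e-9)

    def test_rhs_matches_dense_assembly(self, assembled):
        op, _, rhs, cg, phen, traits = assembled
        np.testing.assert_allclose(op.rhs(phen.yd), rhs, rtol=1e-12)

    def test_symmetry_on_random_pairs(self, rng, assembled):
        op = assembled[0]
        for _ in range(20):
            v = rng.standard_normal(op.n_unknowns)
            u = rng.standard_normal(op.n_unknowns)
            assert op.matvec(v) @ u == pytest.approx(op.matvec(u) @ v,
                                                     rel=1e-8)

    def test_zero_vector(self, assembled):
        op = assembled[0]
        np.testing.assert_array_equal(op.matvec(np.zeros(op.n_unknowns)),
                                      np.zeros(op.n_unknowns))

    def test_dimension_mismatch(self, assembled):
        with pytest.raises(ValidationError):
            assembled[0].matvec(np.zeros(3))


class TestPreconditioner:
    def test_blocks_equal_dense_diagonal_blocks(self, rng, assembled):
        op, A, *_ = assembled
        T = op.T
        precond = block_preconditioner(op)
        # applying the preconditioner to a basis vector of one level must
        # equal the inverse of that level's dense diagonal block
        n_levels = 1 + op.n_animals + op.n_snps
        for level in range(n_levels):
            sl = slice(level * T, (level + 1) * T)
            dense_block_inv = np.linalg.inv(A[sl, sl])
            for t in range(T):
                e = np.zeros(op.n_unknowns)
                e[level * T + t] = 1.0
                np.testing.assert_allclose(precond(e)[sl],
                                           dense_block_inv[:, t],
                                           rtol=1e-9, atol=1e-12)

    def test_applying_twice_equals_squared_inverse(self, rng, assembled):
        op, A, *_ = assembled
        T = op.T
        precond = block_preconditioner(op)
        Minv = np.zeros_like(A)
        n_levels = 1 + op.n_animals + op.n_snps
        for level in range(n_levels):
            sl = slice(level * T, (level + 1) * T)
            Minv[sl, sl] = np.linalg.inv(A[sl, sl])
        v = rng.standard_normal(op.n_unknowns)
        np.testing.assert_allclose(precond(precond(v)), Minv @ Minv @ v,
                                   rtol=1e-8, atol=1e-10)


class TestSolve:
    def test_pcg_matches_dense_direct_solve(self, assembled):
        op, A, rhs, cg, phen, traits = assembled
        x, report = pcg_solve(op, op.rhs(phen.yd), tolerance=1e-12)
        assert report.converged
        x_dense = np.linalg.solve(A, rhs)
        np.testing.assert_allclose(x, x_dense, rtol=1e-7, atol=1e-10)

    def test_larger_instance_oracle(self, rng):
        panel = random_panel(rng, n_animals=20, n_snps=30, n_chrom=3)
        traits = TraitModel(
            ["a", "b", "c"],
            np.array([[0.3, 0.1, 0.05], [0.1, 0.25, 0.02],
                      [0.05, 0.02, 0.2]]),
            np.array([[0.8, 0.2, -0.1], [0.2, 0.9, 0.1], [-0.1, 0.1, 0.7]]),
        )
        cg = center_genotypes(panel)
        w = rng.uniform(0.5, 1.5, size=20)
        Y = rng.standard_normal((20, 3))
        prior = build_prior("unweighted", traits, cg.scale_sum,
                            n_snps=cg.n_snps)
        model = SnpBlup(R=traits.R, prior=prior, tolerance=1e-12).fit(
            cg.matrix, Y, sample_weight=w)
        A, Re_inv, X = dense_mme(cg.matrix, traits.R, w, prior.blocks, 0.01)
        sol = np.linalg.solve(
            A, dense_rhs(Re_inv, X, Y, cg.n_snps, 3))
        T, n = 3, 20
        np.testing.assert_allclose(model.mu_hat_, sol[:T], rtol=1e-6,
                                   atol=1e-9)
        np.testing.assert_allclose(model.u_hat_.ravel(),
                                   sol[T:T + n * T], rtol=1e-6, atol=1e-9)
        np.testing.assert_allclose(model.b_hat_.ravel(), sol[T + n * T:],
                                   rtol=1e-6, atol=1e-9)

    def test_solution_invariant_to_snp_permutation(self, rng, tiny_instance):
        panel, phen, traits = tiny_instance
        cg = center_genotypes(panel)
        prior = build_prior("unweighted", traits, cg.scale_sum,
                            n_snps=cg.n_snps)
        m1 = SnpBlup(R=traits.R, prior=prior, tolerance=1e-11).fit(
            cg.matrix, phen.yd, sample_weight=phen.record_weight)
        perm = rng.permutation(cg.n_snps)
        prior_p = build_prior("unweighted", traits, cg.scale_sum,
                              n_snps=cg.n_snps)
        prior_p.blocks = prior.blocks[perm]
        m2 = SnpBlup(R=traits.R, prior=prior_p, tolerance=1e-11).fit(
            cg.matrix[:, perm], phen.yd, sample_weight=phen.record_weight)
        np.testing.assert_allclose(m1.b_hat_[perm], m2.b_hat_, atol=1e-8)
        np.testing.assert_allclose(m1.u_hat_, m2.u_hat_, atol=1e-8)

    def test_true_residual_history_non_increasing(self, rng):
        panel = random_panel(rng, n_animals=15, n_snps=20, n_chrom=2)
        traits = TraitModel(["a"], np.array([[0.3]]), np.array([[0.7]]))
        cg = center_genotypes(panel)
        prior = build_prior("unweighted", traits, cg.scale_sum,
                            n_snps=cg.n_snps)
        op = MmeOperator(cg.matrix, traits.R, np.ones(15), prior, 0.01)
        _, report = pcg_solve(op, op.rhs(rng.standard_normal((15, 1))),
                              tolerance=1e-12, check_interval=5)
        hist = np.array(report.rel_residual_history)
        assert np.all(np.diff(hist) <= 1e-12)

    def test_max_iter_returns_unconverged(self, assembled):
        op, _, _, cg, phen, traits = assembled
        x, report = pcg_solve(op, op.rhs(phen.yd), tolerance=1e-13,
                              max_iter=2)
        assert not report.converged
        assert report.iterations == 2

    def test_unweighted_matches_gblup_oracle(self, rng, tiny_instance):
        """With a common prior block the augmented SNP model reproduces the
        equivalent animal-model (GBLUP) with K = MM' (x) V_SNP + eps I."""
        panel, phen, traits = tiny_instance
        cg = center_genotypes(panel)
        eps = 0.01
        prior = build_prior("unweighted", traits, cg.scale_sum,
                            n_snps=cg.n_snps)
        model = SnpBlup(R=traits.R, prior=prior, epsilon=eps,
                        tolerance=1e-12).fit(
            cg.matrix, phen.yd, sample_weight=phen.record_weight)

        M = cg.matrix
        n, T = M.shape[0], traits.n_traits
        Ku = np.kron(M @ M.T, prior.base_V) + eps * np.eye(n * T)
        Re_inv = np.kron(np.diag(phen.record_weight),
                         np.linalg.inv(traits.R))
        X = np.tile(np.eye(T), (n, 1))
        top = np.hstack([X.T @ Re_inv @ X, X.T @ Re_inv])
        bot = np.hstack([Re_inv @ X, Re_inv + np.linalg.inv(Ku)])
        lhs = np.vstack([top, bot])
        rhs = np.concatenate([X.T @ Re_inv @ phen.yd.ravel(),
                              Re_inv @ phen.yd.ravel()])
        sol = np.linalg.solve(lhs, rhs)
        np.testing.assert_allclose(model.mu_hat_, sol[:T], atol=1e-6)
        np.testing.assert_allclose(model.u_hat_.ravel(), sol[T:], atol=1e-6)

    def test_epsilon_limit_u_approaches_mb(self, tiny_instance):
        """u = Zb holds exactly only in the eps -> 0 limit; the relative gap
        must shrink (roughly linearly in eps) as the coupling tightens."""
        panel, phen, traits = tiny_instance
        cg = center_genotypes(panel)
        gaps = []
        for eps in (0.01, 0.001, 0.0001):
            prior = build_prior("unweighted", traits, cg.scale_sum,
                                n_snps=cg.n_snps)
            m = SnpBlup(R=traits.R, prior=prior, epsilon=eps,
                        tolerance=1e-10).fit(
                cg.matrix, phen.yd, sample_weight=phen.record_weight)
            gap = np.linalg.norm(m.u_hat_ - cg.matrix @ m.b_hat_) \
                / np.linalg.norm(m.u_hat_)
            gaps.append(gap)
        assert gaps[0] > gaps[1] > gaps[2]
        assert gaps[2] < 0.005


class TestPredict:
    def test_zero_effects(self, rng):
        assert np.all(predict(np.zeros((4, 3)),
                              rng.standard_normal((5, 4))) == 0)

    def test_forced_arithmetic(self):
        g = predict(np.array([[1.0, 0.0, 0.0]]), np.array([[0.5]]))
        np.testing.assert_allclose(g, [[0.5, 0.0, 0.0]])

    def test_snp_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            predict(np.zeros((4, 2)), np.zeros((3, 5)))

    def test_training_predictions_near_u_hat(self, tiny_instance):
        panel, phen, traits = tiny_instance
        cg = center_genotypes(panel)
        prior = build_prior("unweighted", traits, cg.scale_sum,
                            n_snps=cg.n_snps)
        m = SnpBlup(R=traits.R, prior=prior, epsilon=0.001,
                    tolerance=1e-11).fit(
            cg.matrix, phen.yd, sample_weight=phen.record_weight)
        gap = np.linalg.norm(m.u_hat_ - m.predict(cg.matrix)) \
            / np.linalg.norm(m.u_hat_)
        assert gap < 0.01
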