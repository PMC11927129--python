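"""Augmented multitrait SNP-BLUP mixed-model equations and their PCG solver.

The model is ``y = Xμ + Zb + e`` with ``Z = M ⊗ I_T`` (M the centred allele
counts), ``e ~ N(0, W ⊗ R)`` where ``W = diag(1/w_i)``, and per-SNP prior
blocks ``b_j ~ N(0, V_SNP_j)`` collected in the block-diagonal Θ.  Breeding
values ``u = Zb`` are carried explicitly, with a small ε·I regularising their
joint covariance with b, which yields the three-block symmetric system

    [ X'(W⁻¹⊗R⁻¹)X   X'(W⁻¹⊗R⁻¹)          0          ] [μ]   [X'(W⁻¹⊗R⁻¹)y]
    [ (W⁻¹⊗R⁻¹)X     (W⁻¹⊗R⁻¹)+I/ε       −Z/ε        ] [u] = [(W⁻¹⊗R⁻¹)y  ]
    [ 0              −Z'/ε                Z'Z/ε + Θ⁻¹ ] [b]   [0           ]

solved matrix-free by preconditioned conjugate gradients with a block-Jacobi
preconditioner (the inverted T×T diagonal block of each effect level).
Convergence is declared when the Euclidean norm of the true residual relative
to that of the right-hand side drops below the tolerance (default 1e−9); the
true residual is recomputed periodically to guard against drift of the
recursive PCG residual.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

from .datamodel import FitResult, ValidationError
from .weights import SnpPrior

logger = logging.getLogger("gwablup")


@dataclass
class SolverReport:
    iterations: int
    rel_residual_history: list[float]
    converged: bool
    tolerance: float


class MmeOperator:
    """Matrix-free application of the augmented MME coefficient matrix.

    Unknowns are stacked as [μ (T) | u (n_a·T, trait-minor) | b (N·T,
    trait-minor)]; Z and Z'Z are never materialised.
    """

    def __init__(
        self,
        M: np.ndarray,
        R: np.ndarray,
        record_weight: np.ndarray,
        prior: SnpPrior,
        epsilon: float = 0.01,
    ):
        self.M = np.asarray(M, dtype=float)
        self.n_animals, self.n_snps = self.M.shape
        if prior.n_snps != self.n_snps:
            raise ValidationError(
                f"prior has {prior.n_snps} blocks for {self.n_snps} SNPs"
            )
        if not (epsilon > 0):
            raise ValidationError("epsilon must be positive")
        self.R = np.asarray(R, dtype=float)
        self.T = self.R.shape[0]
        self.R_inv = np.linalg.inv(self.R)
        self.w = np.asarray(record_weight, dtype=float)
        if self.w.shape != (self.n_animals,) or np.any(self.w <= 0):
            raise ValidationError("record weights must be positive, one per animal")
        self.epsilon = float(epsilon)
        self.prior = prior
        self.theta_inv = prior.block_inverses()          # (N, T, T)
        self.col_sq = np.einsum("ij,ij->j", self.M, self.M)  # diag of M'M

    @property
    def n_unknowns(self) -> int:
        return self.T * (1 + self.n_animals + self.n_snps)

    def split(self, x: np.ndarray):
        T, n, N = self.T, self.n_animals, self.n_snps
        return (
            x[:T],
            x[T:T + n * T].reshape(n, T),
            x[T + n * T:].reshape(N, T),
        )

    def matvec(self, x: np.ndarray) -> np.ndarray:
        if x.shape != (self.n_unknowns,):
            raise ValidationError(
                f"vector of length {x.shape} for operator of size {self.n_unknowns}"
            )
        mu, U, B = self.split(x)
        w, Rinv, eps = self.w, self.R_inv, self.epsilon

        wU = w[:, None] * U
        out_mu = Rinv @ (w.sum() * mu + wU.sum(axis=0))
        MB = self.M @ B
        out_U = (wU + np.outer(w, mu)) @ Rinv + U / eps - MB / eps
        out_B = (self.M.T @ (MB - U)) / eps + np.einsum(
            "jts,js->jt", self.theta_inv, B
        )
        return np.concatenate([out_mu, out_U.ravel(), out_B.ravel()])

    def rhs(self, Y: np.ndarray) -> np.ndarray:
        Y = np.asarray(Y, dtype=float)
        if Y.shape != (self.n_animals, self.T):
            raise ValidationError("phenotypes must be (n_animals, T)")
        wY = self.w[:, None] * Y
        r_mu = self.R_inv @ wY.sum(axis=0)
        r_U = wY @ self.R_inv
        return np.concatenate([r_mu, r_U.ravel(), np.zeros(self.n_snps * self.T)])


def block_preconditioner(operator: MmeOperator):
    """Block-Jacobi preconditioner from the inverted per-level T×T diagonal
    blocks of the MME (one block for the means, one per animal, one per SNP).
    Singular blocks are regularised by adding ``1e-8·trace/T`` to their
    diagonal before inversion."""
    T, eps = operator.T, operator.epsilon
    I = np.eye(T)
    mu_block = operator.w.sum() * operator.R_inv
    u_blocks = operator.w[:, None, None] * operator.R_inv[None] + I / eps
    b_blocks = operator.col_sq[:, None, None] / eps * I + operator.theta_inv

    def _inv(stack: np.ndarray) -> np.ndarray:
        wmin = np.linalg.eigvalsh(stack)[..., 0]
        bad = wmin <= 0
        if np.any(bad):
            logger.warning("regularised %d singular preconditioner block(s)",
                           int(np.sum(bad)))
            stack = stack.copy()
            tr = np.einsum("...tt->...", stack[bad]) / T
            stack[bad] += (1e-8 * tr)[..., None, None] * I
        return np.linalg.inv(stack)

    mu_inv = _inv(mu_block[None])[0]
    u_inv = _inv(u_blocks)
    b_inv = _inv(b_blocks)

    def apply(x: np.ndarray) -> np.ndarray:
        mu, U, B = operator.split(x)
        return np.concatenate([
            mu_inv @ mu,
            np.einsum("its,is->it", u_inv, U).ravel(),
            np.einsum("jts,js->jt", b_inv, B).ravel(),
        ])

    return apply


def pcg_solve(
    operator: MmeOperator,
    rhs: np.ndarray,
    tolerance: float = 1e-9,
    max_iter: int = 20000,
    check_interval: int = 50,
) -> tuple[np.ndarray, SolverReport]:
    """Preconditioned conjugate gradients on the MME, from a zero start.

    The recursive residual drives the iteration; every ``check_interval``
    iterations (and whenever the recursive norm reaches the tolerance) the
    true residual ``rhs − A x`` is recomputed, and convergence is only
    declared on the true relative residual.
    """
    precond = block_preconditioner(operator)
    rhs_norm = float(np.linalg.norm(rhs))
    if rhs_norm == 0.0:
        return np.zeros_like(rhs), SolverReport(0, [0.0], True, tolerance)
    x = np.zeros_like(rhs)
    r = rhs.copy()
    z = precond(r)
    p = z
    rz = float(r @ z)
    history: list[float] = []
    best_x, best_rel = x.copy(), np.inf
    it = 0
    while it < max_iter:
        it += 1
        Ap = operator.matvec(p)
        alpha = rz / float(p @ Ap)
        x += alpha * p
        r -= alpha * Ap
        rel = float(np.linalg.norm(r)) / rhs_norm
        if rel < tolerance or it % check_interval == 0:
            r = rhs - operator.matvec(x)  # true residual
            rel = float(np.linalg.norm(r)) / rhs_norm
            history.append(rel)
            if rel < best_rel:
                best_rel, best_x = rel, x.copy()
            if rel < tolerance:
                return x, SolverReport(it, history, True, tolerance)
            if rel > 10.0 * best_rel:
                # rounding has broken conjugacy beyond repair; keep the best
                logger.warning(
                    "PCG stagnated at iteration %d (best rel residual %.3e)",
                    it, best_rel)
                history.append(best_rel)
                return best_x, SolverReport(
                    it, history, best_rel < tolerance, tolerance)
        z = precond(r)
        rz_new = float(r @ z)
        p = z + (rz_new / rz) * p
        rz = rz_new
    rel = float(np.linalg.norm(rhs - operator.matvec(x))) / rhs_norm
    if rel < best_rel:
        best_rel, best_x = rel, x
    history.append(best_rel)
    if best_rel >= tolerance:
        logger.warning("PCG stopped at max_iter=%d with rel residual %.3e",
                       max_iter, best_rel)
    return best_x, SolverReport(max_iter, history,
                                best_rel < tolerance, tolerance)


class SnpBlup(RegressorMixin, BaseEstimator):
    """Multitrait SNP-BLUP with per-SNP prior covariance blocks.

    Parameters
    ----------
    R : (T, T) array
        Residual covariance of the traits.
    prior : SnpPrior
        Per-SNP prior covariance blocks (any weighting scheme).
    epsilon : float, default 0.01
        Regularisation coupling breeding values to SNP effects.
    tolerance : float, default 1e-9
        Relative-residual convergence criterion of the PCG solver.

    Attributes
    ----------
    mu_hat_ : (T,) trait means; u_hat_ : (n, T) training breeding values;
    b_hat_ : (N, T) SNP effects; n_iter_, rel_residual_, converged_, report_.
    """

    def __init__(
        self,
        R: np.ndarray | None = None,
        prior: SnpPrior | None = None,
        epsilon: float = 0.01,
        tolerance: float = 1e-9,
        max_iter: int = 20000,
        check_interval: int = 50,
    ):
        self.R = R
        self.prior = prior
        self.epsilon = epsilon
        self.tolerance = tolerance
        self.max_iter = max_iter
        self.check_interval = check_interval

    def fit(self, X: np.ndarray, y: np.ndarray, sample_weight=None) -> "SnpBlup":
        """Solve the MME for centred training genotypes X (n, N) and
        phenotypes y (n, T); ``sample_weight`` holds the record weights."""
        if self.R is None or self.prior is None:
            raise ValidationError("SnpBlup requires R and a SnpPrior")
        X = np.asarray(X, dtype=float)
        y = np.atleast_2d(np.asarray(y, dtype=float))
        n = X.shape[0]
        w = np.ones(n) if sample_weight is None else np.asarray(sample_weight, float)
        op = MmeOperator(X, self.R, w, self.prior, self.epsilon)
        sol, report = pcg_solve(
            op, op.rhs(y), self.tolerance, self.max_iter, self.check_interval
        )
        mu, U, B = op.split(sol)
        self.operator_ = op
        self.mu_hat_ = mu.copy()
        self.u_hat_ = U.copy()
        self.b_hat_ = B.copy()
        self.n_iter_ = report.iterations
        self.rel_residual_ = report.rel_residual_history[-1]
        self.converged_ = report.converged
        self.report_ = report
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Genomic values ``Z_v b̂`` for centred genotypes X (n_v, N)."""
        return predict(self.b_hat_, X)

    def fit_result(self, scheme: str = "", trait_names=None) -> FitResult:
        return FitResult(
            self.mu_hat_, self.u_hat_, self.b_hat_,
            self.n_iter_, self.rel_residual_, self.converged_,
            scheme or self.prior.scheme, list(trait_names or []),
        )


def predict(b_hat: np.ndarray, centered_validation: np.ndarray) -> np.ndarray:
    """Genomic predictions ``ĝ_v = Z_v b̂`` from centred validation genotypes
    (centred with *training* allele frequencies)."""
    b_hat = np.asarray(b_hat, dtype=float)
    Zv = np.asarray(centered_validation, dtype=float)
    if Zv.shape[1] != b_hat.shape[0]:
        raise ValidationError(
            f"validation panel has {Zv.shape[1]} SNPs but b_hat has "
            f"{b_hat.shape[0]}"
        )
    return Zv @ b_hat
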