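"""Canonical transformation of correlated traits.

The canonical transformation maps T genetically and environmentally
correlated traits onto T new traits that are mutually independent both
genetically and environmentally: the transform ``Q`` simultaneously
diagonalises the residual covariance to the identity (``Q R Qᵀ = I``) and the
genetic covariance to ``diag(λ)`` (``Q G Qᵀ = diag(λ)``).  The λ are the
generalized eigenvalues of the pencil (G, R) and act as the genetic variances
of the canonical traits against unit environmental variance.  Single-trait
association scans of canonical traits are then statistically independent, and
their effect estimates can be mapped back to the original trait scale with
``Q⁻¹``.
"""

from __future__ import annotations

import numpy as np
import scipy.linalg
from sklearn.base import BaseEstimator, TransformerMixin

from .datamodel import TraitModel, ValidationError


def bend_to_positive_definite(S: np.ndarray, min_eigenvalue: float) -> np.ndarray:
    """Repair a symmetric matrix by clipping its eigenvalues from below.

    Returns ``S`` unchanged (up to symmetrisation) when all eigenvalues
    already reach ``min_eigenvalue``; otherwise eigenvalues are floored and
    the matrix reassembled, the minimal perturbation in the eigenvalue metric.
    """
    S = np.asarray(S, dtype=float)
    if not np.allclose(S, S.T, atol=1e-8):
        raise ValidationError("bend_to_positive_definite expects a symmetric matrix")
    S = 0.5 * (S + S.T)
    w, V = np.linalg.eigh(S)
    if w.min() >= min_eigenvalue:
        return S
    w = np.maximum(w, min_eigenvalue)
    out = (V * w) @ V.T
    return 0.5 * (out + out.T)


class CanonicalTransformer(TransformerMixin, BaseEstimator):
    """Whitening transform to genetically and environmentally independent traits.

    Parameters
    ----------
    G, R : (T, T) arrays
        Genetic and residual trait covariance matrices; both must be positive
        definite (bend first if built from rounded published correlations).

    Attributes
    ----------
    Q_ : (T, T) array
        Row-wise transform; canonical records are ``y_c = Q_ @ y``.
    Q_inv_ : (T, T) array
        Inverse transform back to the original trait scale.
    canonical_genetic_var_ : (T,) array
        Genetic variances λ of the canonical traits, ascending.
    """

    def __init__(self, G: np.ndarray | None = None, R: np.ndarray | None = None):
        self.G = G
        self.R = R

    def fit(self, X=None, y=None) -> "CanonicalTransformer":
        if self.G is None or self.R is None:
            raise ValidationError("CanonicalTransformer requires G and R")
        G = np.asarray(self.G, dtype=float)
        R = np.asarray(self.R, dtype=float)
        try:
            # eigh on the pencil (G, R): V' R V = I, V' G V = diag(w), w ascending
            w, V = scipy.linalg.eigh(G, R)
        except scipy.linalg.LinAlgError as e:
            raise ValidationError(f"generalized eigenproblem failed: {e}") from e
        if w.min() <= 0:
            raise ValidationError(
                f"G is not positive definite against R (eigenvalues {w})"
            )
        Q = V.T
        # sign convention: largest-magnitude entry of each row positive
        signs = np.sign(Q[np.arange(Q.shape[0]), np.argmax(np.abs(Q), axis=1)])
        Q = Q * signs[:, None]
        self._assert_invariants(Q, G, R, w)
        self.Q_ = Q
        self.Q_inv_ = np.linalg.inv(Q)
        self.canonical_genetic_var_ = w
        return self

    @staticmethod
    def _assert_invariants(Q, G, R, w, tol: float = 1e-8) -> None:
        T = Q.shape[0]
        qrq = Q @ R @ Q.T
        qgq = Q @ G @ Q.T
        err_r = np.max(np.abs(qrq - np.eye(T)))
        err_g = np.max(np.abs(qgq - np.diag(w)))
        scale = max(1.0, float(np.max(np.abs(w))))
        if err_r > tol or err_g > tol * scale:
            raise ValidationError(
                "canonical transform failed its invariants: "
                f"|QRQ'-I|={err_r:.2e}, |QGQ'-diag(lambda)|={err_g:.2e}, "
                f"eigenvalues={w}"
            )

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Map rows of original-trait records to canonical traits."""
        X = np.asarray(X, dtype=float)
        if X.shape[-1] != self.Q_.shape[1]:
            raise ValidationError(
                f"records have {X.shape[-1]} traits, transform expects "
                f"{self.Q_.shape[1]}"
            )
        return X @ self.Q_.T

    def inverse_transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.shape[-1] != self.Q_inv_.shape[1]:
            raise ValidationError("dimension mismatch in inverse_transform")
        return X @ self.Q_inv_.T

    def to_frame(self):
        """Persistable table of Q and λ (one row per canonical trait)."""
        import pandas as pd

        T = self.Q_.shape[0]
        df = pd.DataFrame(self.Q_, columns=[f"q{t}" for t in range(T)])
        df.insert(0, "canonical_trait", np.arange(T))
        df["genetic_variance"] = self.canonical_genetic_var_
        return df


def build_canonical_transform(traits: TraitModel) -> CanonicalTransformer:
    """Fit the canonical transform for a trait model (G, R must be PD)."""
    return CanonicalTransformer(G=traits.G, R=traits.R).fit()


def transform_phenotypes(yd: np.ndarray, transform: CanonicalTransformer) -> np.ndarray:
    return transform.transform(yd)


def back_transform_effects(
    canonical_effects: np.ndarray,
    canonical_se: np.ndarray,
    transform: CanonicalTransformer,
) -> tuple[np.ndarray, np.ndarray]:
    """Map per-SNP canonical effect estimates and standard errors to the
    original trait scale.

    For SNP j, ``b_orig = Q⁻¹ b_canonical`` and the sampling covariance is
    ``Q⁻¹ diag(se²) Q⁻ᵀ`` (canonical estimates are independent across
    canonical traits by construction); the reported standard error is the
    square root of its diagonal.  Degenerate canonical entries (NaN se) yield
    NaN original-scale entries, to be handled by the weighting stage.
    """
    eff = np.asarray(canonical_effects, dtype=float)
    se = np.asarray(canonical_se, dtype=float)
    if eff.shape != se.shape:
        raise ValidationError("effects and standard errors must share a shape")
    finite = np.isfinite(se)
    if np.any(se[finite] <= 0):
        raise ValidationError("canonical standard errors must be positive")
    Qi = transform.Q_inv_
    eff_orig = eff @ Qi.T
    se_orig = np.sqrt(se**2 @ (Qi**2).T)
    return eff_orig, se_orig
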