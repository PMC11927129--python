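"""Single-SNP weighted association scans of canonical traits.

Because canonical traits are genetically and environmentally independent,
each is scanned separately with a single-SNP weighted least-squares model
``y_i = a + b x_ij + e_i`` with record weights ``w_i`` (residual variance
proportional to ``1/w_i``).  The slope and its standard error feed the
likelihood-ratio weighting; the residual variance is estimated per SNP with
an ``n - 2`` denominator.  The scan is vectorised over SNPs and its results
are independent of animal ordering and of any chunking of the SNP axis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .datamodel import CenteredGenotypes, ValidationError

logger = logging.getLogger("gwablup")


@dataclass
class GwasResult:
    """Per-SNP, per-trait effect estimates and standard errors.

    Degenerate SNPs (no genotype variance after weighting, or an exact fit
    with zero residual variance) carry NaN standard errors and are excluded
    from weighting by downstream code.
    """

    snp_ids: np.ndarray
    effects: np.ndarray  # (N_snps, T)
    se: np.ndarray       # (N_snps, T); NaN marks a degenerate fit
    trait_scale: str     # "canonical" or "original"

    def __post_init__(self) -> None:
        if self.trait_scale not in ("canonical", "original"):
            raise ValidationError(f"unknown trait_scale {self.trait_scale!r}")
        if self.effects.shape != self.se.shape:
            raise ValidationError("effects and se shapes differ")
        finite = np.isfinite(self.se)
        if np.any(self.se[finite] <= 0):
            raise ValidationError("standard errors must be positive where defined")

    @property
    def n_traits(self) -> int:
        return self.effects.shape[1]

    @property
    def ok(self) -> np.ndarray:
        """Boolean (N_snps, T): True where the fit was non-degenerate."""
        return np.isfinite(self.se) & (self.se > 0)


def single_snp_scan(
    centered: CenteredGenotypes | np.ndarray,
    phenotypes: np.ndarray,
    record_weight: np.ndarray | None = None,
    trait_scale: str = "canonical",
    snp_ids: np.ndarray | None = None,
) -> GwasResult:
    """Weighted least-squares scan of each trait column on each SNP column.

    Parameters
    ----------
    centered : CenteredGenotypes or (n, N) array
        Centred training genotypes.
    phenotypes : (n, T) array
        Trait records (canonical-scale yield deviations in the standard
        workflow) of the same animals.
    record_weight : (n,) array, optional
        WLS weights w_i; defaults to 1 (ordinary least squares).
    """
    if isinstance(centered, CenteredGenotypes):
        X = centered.matrix
        if snp_ids is None:
            snp_ids = centered.snp_map["snp_id"].to_numpy()
    else:
        X = np.asarray(centered, dtype=float)
        if snp_ids is None:
            snp_ids = np.arange(X.shape[1])
    Y = np.atleast_2d(np.asarray(phenotypes, dtype=float))
    n, N = X.shape
    if Y.shape[0] != n:
        raise ValidationError(f"{Y.shape[0]} phenotype rows for {n} genotype rows")
    if n < 3:
        raise ValidationError("need at least 3 animals for a slope and its se")
    w = np.ones(n) if record_weight is None else np.asarray(record_weight, float)
    if w.shape != (n,) or np.any(w <= 0):
        raise ValidationError("record weights must be positive, one per animal")

    sw = w.sum()
    Yc = Y - (w @ Y) / sw            # re-centre at the weighted mean
    wYc = w[:, None] * Yc
    syy = np.einsum("it,it->t", wYc, Yc)
    # per-SNP loop: every statistic of SNP j is reduced from that column's
    # data alone, so chunked scans are bit-identical to a joint scan
    T = Y.shape[1]
    sxx = np.empty(N)
    sxy = np.empty((N, T))
    for j in range(N):
        xj = np.ascontiguousarray(X[:, j])  # stride-free: chunk-invariant BLAS
        xc = xj - np.dot(w, xj) / sw
        sxx[j] = np.dot(w * xc, xc)
        sxy[j] = xc @ wYc

    varying = sxx > 1e-16 * n        # allele-count scale; chunk-invariant
    slope = np.zeros((N, Y.shape[1]))
    np.divide(sxy, sxx[:, None], out=slope, where=varying[:, None])
    rss = np.maximum(syy[None, :] - slope**2 * sxx[:, None], 0.0)
    sigma2 = rss / (n - 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(sigma2 / sxx[:, None])
    # degenerate: no genotype variance, or an exact fit (zero residual)
    degenerate = ~varying[:, None] | (rss <= 1e-12 * np.maximum(syy[None, :], 1e-300))
    if degenerate.any():
        logger.warning(
            "flagged %d degenerate SNP-trait fit(s); excluded from weighting",
            int(degenerate.sum()),
        )
        se = np.where(degenerate, np.nan, se)
        slope = np.where(~varying[:, None], np.nan, slope)
    return GwasResult(np.asarray(snp_ids), slope, se, trait_scale)
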