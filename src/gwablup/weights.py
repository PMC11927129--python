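"""GWAS-derived SNP weights and per-SNP prior covariance blocks.

The weighting chain mimics the model averaging of Bayesian variable-selection
predictors with deterministic quantities: each SNP × trait association is
summarised by a log-likelihood ratio ``LR = ½ (b̂/se)²``, smoothed along the
chromosome with a 5-SNP moving average (an LD proxy; windows never cross
chromosome boundaries), and converted into the posterior probability of a
non-zero effect under a point-mass mixture prior with ``π = 0.001``:

    PP = π e^LR / (π e^LR + 1 − π).

The three weighting schemes then build per-SNP T×T prior covariance blocks
from the base matrix ``V_SNP = G / Σ 2p_j(1−p_j)``:

* ``unweighted``      — every block equals V_SNP;
* ``equal_weights``   — V_SNP · PP_j / mean(PP_j), with PP_j from the summed
  canonical-trait LRs (one weight shared by all traits);
* ``trait_specific``  — S_j V_SNP S_j with S_j = diag √(PP_tj / meanⱼ PP_tj),
  rescaling per-trait variances while preserving the correlations of V_SNP.

Mean-normalising by mean(PP) conserves the total prior genetic variance per
trait across schemes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .canonical import CanonicalTransformer, back_transform_effects
from .datamodel import TraitModel, ValidationError
from .gwas import GwasResult

SCHEMES = ("unweighted", "equal_weights", "trait_specific")
_SCHEME_ALIASES = {"unw": "unweighted", "eqw": "equal_weights", "tsw": "trait_specific"}


def canonical_scheme(name: str) -> str:
    s = _SCHEME_ALIASES.get(name, name)
    if s not in SCHEMES:
        raise ValidationError(f"unknown weighting scheme {name!r}")
    return s


def loglik_ratio(effect, se):
    """Log-likelihood ratio ``0.5 (effect/se)^2`` of a non-zero SNP effect."""
    effect = np.asarray(effect, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se[np.isfinite(se)] <= 0):
        raise ValidationError("standard errors must be strictly positive")
    return 0.5 * (effect / se) ** 2


def moving_average_by_chromosome(
    values: np.ndarray, snp_map: pd.DataFrame, half_window: int = 2
) -> np.ndarray:
    """Moving average of per-SNP values over ``2*half_window + 1`` map-adjacent
    SNPs, truncated at chromosome ends (the divisor is the actual window size);
    windows never cross a chromosome boundary."""
    if half_window < 0:
        raise ValidationError("half_window must be >= 0")
    values = np.asarray(values, dtype=float)
    squeeze = values.ndim == 1
    V = values[:, None] if squeeze else values
    if V.shape[0] != len(snp_map):
        raise ValidationError("values length does not match the SNP map")
    if half_window == 0:
        out = V.copy()
        return out[:, 0] if squeeze else out
    out = np.empty_like(V)
    chrom = snp_map["chromosome"].astype(str).to_numpy()
    for c in pd.unique(chrom):
        idx = np.flatnonzero(chrom == c)
        L = idx.size
        cs = np.cumsum(V[idx], axis=0)
        j = np.arange(L)
        lo = np.maximum(j - half_window, 0)
        hi = np.minimum(j + half_window, L - 1)
        sums = cs[hi] - np.where((lo > 0)[:, None],
                                 cs[np.maximum(lo - 1, 0)], 0.0)
        out[idx] = sums / (hi - lo + 1)[:, None]
    return out[:, 0] if squeeze else out


def posterior_probability(lr_smoothed, pi: float = 0.001):
    """Posterior probability of a non-zero SNP effect given a smoothed LR.

    Evaluates ``π e^LR / (π e^LR + 1 − π)`` directly for moderate LR and via
    the logistic function ``σ(LR + logit π)`` for large LR so that LRs in the
    hundreds or thousands never overflow; the result is clamped to the open
    interval (0, 1).  At ``LR = 0`` the value is exactly the prior π.
    """
    if not (0.0 < pi < 1.0):
        raise ValidationError("pi must lie strictly in (0,1)")
    lr = np.asarray(lr_smoothed, dtype=float)
    if np.any(lr[np.isfinite(lr)] < 0):
        raise ValidationError("smoothed log-likelihood ratios must be nonnegative")
    scalar = lr.ndim == 0
    lr = np.atleast_1d(lr)
    pp = np.empty_like(lr)
    small = lr <= 30.0
    elr = np.exp(lr[small])
    pp[small] = pi * elr / (pi * elr + (1.0 - pi))
    big = ~small
    if big.any():
        # logistic form, immune to overflow of e^LR
        pp[big] = 1.0 / (1.0 + np.exp(-(lr[big] + np.log(pi) - np.log1p(-pi))))
    np.clip(pp, np.nextafter(0.0, 1.0), np.nextafter(1.0, 0.0), out=pp)
    return float(pp[0]) if scalar else pp


@dataclass
class SnpWeightTable:
    """Likelihood ratios, smoothed LRs and posterior probabilities per SNP.

    ``LR``/``LR_smoothed``/``PP`` are on the original trait scale (used by the
    trait-specific scheme); ``PP_combined`` is the single multitrait weight
    built from the sum of the smoothed canonical-trait LRs (equal-weights
    scheme).
    """

    snp_map: pd.DataFrame
    LR: np.ndarray            # (N, T) original-trait LRs
    LR_smoothed: np.ndarray   # (N, T)
    PP: np.ndarray            # (N, T)
    PP_combined: np.ndarray   # (N,)
    pi: float
    trait_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (0.0 < self.pi < 1.0):
            raise ValidationError("pi must lie strictly in (0,1)")
        if np.any(self.PP <= 0) or np.any(self.PP >= 1):
            raise ValidationError("posterior probabilities must lie in (0,1)")
        if np.any(self.LR < 0):
            raise ValidationError("likelihood ratios must be nonnegative")

    @property
    def n_snps(self) -> int:
        return self.LR.shape[0]

    def to_frame(self) -> pd.DataFrame:
        df = self.snp_map.copy()
        names = self.trait_names or [f"trait{t}" for t in range(self.LR.shape[1])]
        for t, name in enumerate(names):
            df[f"LR_{name}"] = self.LR[:, t]
            df[f"LR_smoothed_{name}"] = self.LR_smoothed[:, t]
            df[f"PP_{name}"] = self.PP[:, t]
        df["PP_combined"] = self.PP_combined
        return df


def build_weight_table(
    gwas_canonical: GwasResult,
    transform: CanonicalTransformer,
    snp_map: pd.DataFrame,
    pi: float = 0.001,
    half_window: int = 2,
    trait_names: list[str] | None = None,
) -> SnpWeightTable:
    """Turn a canonical-trait scan into trait-specific and combined weights.

    Canonical-trait LRs are smoothed per canonical trait and summed for the
    combined (equal-weights) posterior probability.  For trait-specific
    weights the canonical effects and standard errors are first back-
    transformed to the original trait scale, then LR → smoothing → PP is
    applied per original trait.  SNPs with degenerate fits contribute LR = 0
    and end up at (approximately) the prior π.
    """
    if gwas_canonical.trait_scale != "canonical":
        raise ValidationError("build_weight_table expects a canonical-scale scan")

    # combined weight: smooth per canonical trait, then sum the smoothed LRs
    lr_canon = np.nan_to_num(
        loglik_ratio(gwas_canonical.effects, gwas_canonical.se), nan=0.0
    )
    lr_canon_sm = moving_average_by_chromosome(lr_canon, snp_map, half_window)
    pp_combined = posterior_probability(lr_canon_sm.sum(axis=1), pi)

    # trait-specific weights on the original scale
    eff_o, se_o = back_transform_effects(
        gwas_canonical.effects, gwas_canonical.se, transform
    )
    lr = np.nan_to_num(loglik_ratio(eff_o, se_o), nan=0.0)
    lr_sm = moving_average_by_chromosome(lr, snp_map, half_window)
    pp = posterior_probability(lr_sm, pi)
    return SnpWeightTable(
        snp_map=snp_map,
        LR=lr,
        LR_smoothed=lr_sm,
        PP=np.atleast_2d(pp),
        PP_combined=np.atleast_1d(pp_combined),
        pi=pi,
        trait_names=trait_names or [],
    )


def base_vsnp(traits: TraitModel, scale_sum: float) -> np.ndarray:
    """Unweighted per-SNP prior covariance ``V_SNP = G / Σ 2 p_j (1 − p_j)``."""
    if not (scale_sum > 0):
        raise ValidationError("scale_sum must be positive")
    return traits.G / scale_sum


@dataclass
class SnpPrior:
    """Per-SNP T×T prior covariance blocks (the direct summands of Θ)."""

    scheme: str
    base_V: np.ndarray    # (T, T)
    blocks: np.ndarray    # (N, T, T), symmetric PSD
    epsilon: float = 0.01

    def __post_init__(self) -> None:
        self.scheme = canonical_scheme(self.scheme)
        if self.blocks.ndim != 3 or self.blocks.shape[1:] != self.base_V.shape:
            raise ValidationError("blocks must be a stack of T x T matrices")

    @property
    def n_snps(self) -> int:
        return self.blocks.shape[0]

    def block_inverses(self, jitter: float = 1e-10) -> np.ndarray:
        """Inverses of every block, with a PSD guard.

        Posterior probabilities near zero make blocks nearly singular; blocks
        whose smallest eigenvalue is not positive get ``jitter * trace`` added
        to their diagonal before inversion.
        """
        blocks = self.blocks
        T = blocks.shape[1]
        wmin = np.linalg.eigvalsh(blocks)[:, 0]
        bad = wmin <= 0
        if bad.any():
            blocks = blocks.copy()
            tr = np.einsum("jtt->j", blocks[bad])
            blocks[bad] += (jitter * tr)[:, None, None] * np.eye(T)
        return np.linalg.inv(blocks)


def build_prior(
    scheme: str,
    traits: TraitModel,
    scale_sum: float,
    weight_table: SnpWeightTable | None = None,
    n_snps: int | None = None,
    epsilon: float = 0.01,
) -> SnpPrior:
    """Assemble the per-SNP prior covariance blocks for a weighting scheme."""
    scheme = canonical_scheme(scheme)
    V = base_vsnp(traits, scale_sum)
    T = V.shape[0]
    if scheme == "unweighted":
        if n_snps is None:
            if weight_table is None:
                raise ValidationError("unweighted prior needs n_snps or a table")
            n_snps = weight_table.n_snps
        blocks = np.broadcast_to(V, (n_snps, T, T)).copy()
        return SnpPrior(scheme, V, blocks, epsilon)
    if weight_table is None:
        raise ValidationError(f"scheme {scheme!r} requires a SnpWeightTable")
    if scheme == "equal_weights":
        w = weight_table.PP_combined / weight_table.PP_combined.mean()
        blocks = V[None, :, :] * w[:, None, None]
    else:  # trait_specific
        if weight_table.PP.shape[1] != T:
            raise ValidationError(
                "trait-specific scheme needs per-original-trait PPs matching G"
            )
        s = np.sqrt(weight_table.PP / weight_table.PP.mean(axis=0))  # (N, T)
        blocks = V[None, :, :] * s[:, :, None] * s[:, None, :]
    return SnpPrior(scheme, V, blocks, epsilon)


def manhattan_plot(weight_table: SnpWeightTable, path) -> None:
    """Per-trait Manhattan plots of posterior probabilities along the genome."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    names = weight_table.trait_names or [
        f"trait{t}" for t in range(weight_table.PP.shape[1])
    ]
    chrom = weight_table.snp_map["chromosome"].astype(str).to_numpy()
    pos = weight_table.snp_map["position"].to_numpy(dtype=float)
    offset, x, ticks = 0.0, np.empty_like(pos), []
    for c in pd.unique(chrom):
        m = chrom == c
        x[m] = pos[m] + offset
        ticks.append((c, float(x[m].mean())))
        offset = float(x[m].max())
    fig, axes = plt.subplots(len(names), 1, figsize=(9, 2.2 * len(names)),
                             sharex=True, squeeze=False)
    for t, (ax, name) in enumerate(zip(axes[:, 0], names)):
        for k, c in enumerate(pd.unique(chrom)):
            m = chrom == c
            ax.scatter(x[m], weight_table.PP[m, t], s=4,
                       color="C0" if k % 2 == 0 else "C1")
        ax.set_ylabel(f"PP ({name})")
        ax.set_ylim(0, 1.02)
    axes[-1, 0].set_xticks([v for _, v in ticks])
    axes[-1, 0].set_xticklabels([c for c, _ in ticks])
    axes[-1, 0].set_xlabel("chromosome")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
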