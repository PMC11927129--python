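"""Synthetic multitrait genotype/phenotype generator with sparse QTL
architectures.

The generator emulates a dairy-cattle-like reference population: biallelic
SNP genotypes with adjacent-marker linkage disequilibrium, a handful of
trait-specific QTL that partially overlap between traits, and multitrait
yield deviations ``y = μ + M b + e`` with residuals drawn per animal from
``R / w_i``.

Genotypes come from a first-order haplotype process: each haplotype is a
latent Gaussian AR(1) chain along the chromosome, thresholded at the quantile
of the per-locus allele frequency, so marginal frequencies are exact and the
``ld_decay`` parameter directly controls adjacent-marker correlation.

Genetic correlations between traits arise from QTL shared between their
architectures.  Effects at a QTL affecting several traits are drawn jointly
with correlation ``r_target / overlap_share``; since the realised genetic
correlation is bounded by the shared-QTL variance fraction, a target
correlation exceeding the configured overlap is infeasible and rejected with
a closed-form check.  Per-trait effect columns are rescaled so the realised
genetic variances match the diagonal of the target G exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats

from .canonical import bend_to_positive_definite
from .datamodel import (
    GenotypePanel,
    PhenotypeTable,
    TraitModel,
    ValidationError,
)

TABLE1_TRAITS = ("Milk", "Protein", "SCC")
TABLE1_H2 = (0.26, 0.20, 0.16)
# residual correlations of the three dairy traits (upper triangle, row-wise)
TABLE1_RESIDUAL_CORR = np.array([
    [1.00, 0.96, -0.17],
    [0.96, 1.00, 0.16],
    [-0.17, 0.16, 1.00],
])
# genetic correlations; the yield-pair value is 0.80, the largest value
# attainable when the two traits share 80% of their QTL (see docs/methods.md)
TABLE1_GENETIC_CORR = np.array([
    [1.00, 0.80, 0.10],
    [0.80, 1.00, 0.10],
    [0.10, 0.10, 1.00],
])


def table1_trait_model() -> TraitModel:
    """Three-trait dairy model (milk/protein yield and somatic cell count)
    with unit phenotypic variances; G and R bent to positive definiteness."""
    return TraitModel.from_correlations(
        TABLE1_TRAITS, TABLE1_H2, TABLE1_GENETIC_CORR, TABLE1_RESIDUAL_CORR
    ).bent()


@dataclass
class SimulationConfig:
    n_animals: int = 3500            # total, incl. the validation animals
    n_validation: int = 500          # the "youngest" animals, masked in training
    n_snps: int = 2000
    n_chromosomes: int = 10
    allele_freq_range: tuple[float, float] = (0.05, 0.95)
    ld_decay: float = 0.7            # adjacent-SNP latent AR(1) correlation
    n_qtl_per_trait: int = 50
    qtl_overlap: np.ndarray | None = None   # (T, T) pairwise shared-QTL fractions
    traits: TraitModel = field(default_factory=table1_trait_model)
    record_weight_range: tuple[float, float] = (1.0, 1.0)
    mu: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        T = self.traits.n_traits
        if self.qtl_overlap is None:
            self.qtl_overlap = np.eye(T)
        self.qtl_overlap = np.asarray(self.qtl_overlap, dtype=float)
        if np.any(self.qtl_overlap < 0) or np.any(self.qtl_overlap > 1):
            raise ValidationError("qtl_overlap fractions must lie in [0,1]")
        if self.n_qtl_per_trait > self.n_snps:
            raise ValidationError("more QTL per trait than SNPs")
        if not (0.0 <= self.ld_decay < 1.0):
            raise ValidationError("ld_decay must lie in [0,1)")
        lo, hi = self.allele_freq_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValidationError("allele_freq_range must lie within (0,1)")

    @property
    def training_ids(self) -> list[str]:
        n_train = self.n_animals - self.n_validation
        return [f"A{i:05d}" for i in range(n_train)]

    @property
    def validation_ids(self) -> list[str]:
        n_train = self.n_animals - self.n_validation
        return [f"A{i:05d}" for i in range(n_train, self.n_animals)]


def simulate_genotypes(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> GenotypePanel:
    """Draw an LD-structured allele-count panel, deterministic given the seed."""
    rng = rng or np.random.default_rng(config.seed)
    lo, hi = config.allele_freq_range
    p = rng.uniform(lo, hi, size=config.n_snps)
    thresholds = scipy.stats.norm.ppf(p)
    rho = config.ld_decay
    n2 = 2 * config.n_animals

    # SNPs spread over chromosomes in contiguous blocks
    sizes = np.full(config.n_chromosomes, config.n_snps // config.n_chromosomes)
    sizes[: config.n_snps % config.n_chromosomes] += 1
    counts = np.empty((config.n_animals, config.n_snps))
    start = 0
    chroms, ids, positions = [], [], []
    for c, L in enumerate(sizes, start=1):
        z = np.empty((n2, L))
        z[:, 0] = rng.standard_normal(n2)
        innov = rng.standard_normal((n2, L - 1)) * np.sqrt(1.0 - rho**2)
        for j in range(1, L):
            z[:, j] = rho * z[:, j - 1] + innov[:, j - 1]
        alleles = z < thresholds[start:start + L]
        counts[:, start:start + L] = (
            alleles[0::2].astype(float) + alleles[1::2].astype(float)
        )
        chroms += [str(c)] * L
        ids += [f"snp{c}_{j + 1}" for j in range(L)]
        positions += [1000 * (j + 1) for j in range(L)]
        start += L
    snp_map = pd.DataFrame(
        {"chromosome": chroms, "snp_id": ids, "position": positions}
    )
    animal_ids = [f"A{i:05d}" for i in range(config.n_animals)]
    return GenotypePanel(animal_ids, snp_map, counts)


@dataclass
class SimulationTruth:
    qtl_indices: list[np.ndarray]       # per trait, indices into the SNP map
    true_effects: np.ndarray            # (N_snps, T), zero off-QTL
    true_breeding_values: np.ndarray    # (n_animals, T)


def _assign_qtl(config: SimulationConfig, rng: np.random.Generator) -> list[np.ndarray]:
    """Pick per-trait QTL index sets with (approximately) the configured
    pairwise sharing; shared SNPs with an earlier trait are drawn from the
    part of that trait's set not already claimed by other traits."""
    T = config.traits.n_traits
    nq = config.n_qtl_per_trait
    all_snps = np.arange(config.n_snps)
    sets: list[np.ndarray] = []
    for t in range(T):
        chosen = np.array([], dtype=int)
        for s in range(t):
            n_share = int(round(config.qtl_overlap[t, s] * nq)) - int(
                np.isin(chosen, sets[s]).sum()
            )
            if n_share <= 0:
                continue
            # prefer SNPs private to trait s so other pairwise overlaps are
            # not inflated; fall back to any unchosen member of sets[s]
            others = ([np.array([], int)] +
                      [sets[r] for r in range(t) if r != s])
            preferred = np.setdiff1d(
                np.setdiff1d(sets[s], np.concatenate(others)), chosen
            )
            pick = rng.choice(preferred, min(n_share, preferred.size),
                              replace=False)
            chosen = np.concatenate([chosen, pick])
            short = n_share - pick.size
            if short > 0:
                fallback = np.setdiff1d(sets[s], chosen)
                chosen = np.concatenate([
                    chosen,
                    rng.choice(fallback, min(short, fallback.size),
                               replace=False),
                ])
        used = np.unique(np.concatenate([chosen] + sets)) if sets else chosen
        free = np.setdiff1d(all_snps, used)
        n_new = nq - chosen.size
        if n_new > free.size:
            raise ValidationError("not enough SNPs for the requested QTL sets")
        if n_new > 0:
            chosen = np.concatenate(
                [chosen, rng.choice(free, n_new, replace=False)]
            )
        sets.append(np.sort(chosen))
    return sets


def _draw_correlation(config: SimulationConfig, qtl_sets) -> np.ndarray:
    """Correlation of joint effect draws at shared QTL, with the closed-form
    feasibility check r_target <= overlap_share."""
    G = config.traits.G
    T = G.shape[0]
    d = np.sqrt(np.diag(G))
    r_target = G / np.outer(d, d)
    C = np.eye(T)
    nq = config.n_qtl_per_trait
    for t in range(T):
        for s in range(t):
            share = np.intersect1d(qtl_sets[t], qtl_sets[s]).size / nq
            if abs(r_target[t, s]) < 1e-12:
                continue
            if share == 0 or abs(r_target[t, s]) > share + 1e-9:
                raise ValidationError(
                    f"target genetic correlation {r_target[t, s]:.2f} between "
                    f"traits {t} and {s} unreachable with QTL overlap "
                    f"{share:.2f}: effects at shared QTL cannot be more than "
                    "perfectly correlated"
                )
            C[t, s] = C[s, t] = np.clip(r_target[t, s] / share, -1.0, 1.0)
    return C


def _mvn_psd(rng: np.random.Generator, C: np.ndarray, size: int) -> np.ndarray:
    """Sample N(0, C) tolerating a singular PSD C (e.g. perfect correlation)."""
    w, V = np.linalg.eigh(C)
    w = np.clip(w, 0.0, None)
    A = V * np.sqrt(w)
    return rng.standard_normal((size, C.shape[0])) @ A.T


def simulate_effects_and_phenotypes(
    panel: GenotypePanel,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[PhenotypeTable, SimulationTruth]:
    """Draw QTL architectures, effects and phenotypes ``y = μ + M b + e``.

    Effect columns are rescaled so the realised genetic variance of every
    trait matches the diagonal of the target G on the simulated sample; the
    realised genetic correlations follow from the QTL sharing.
    """
    rng = rng or np.random.default_rng(config.seed + 1)
    traits = config.traits
    T = traits.n_traits
    n = panel.n_animals
    M = panel.counts - panel.counts.mean(axis=0)

    effects = np.zeros((panel.n_snps, T))
    if config.n_qtl_per_trait > 0:
        qtl_sets = _assign_qtl(config, rng)
        C = _draw_correlation(config, qtl_sets)
        union = np.unique(np.concatenate(qtl_sets))
        member = np.stack([np.isin(union, s) for s in qtl_sets], axis=1)
        raw = _mvn_psd(rng, bend_to_positive_definite(C, 0.0), union.size)
        effects[union] = np.where(member, raw, 0.0)
        g = M @ effects
        sd = g.std(axis=0)
        if np.any(sd == 0):
            raise ValidationError("degenerate genetic values; increase n or QTL")
        effects *= np.sqrt(np.diag(traits.G)) / sd
    else:
        qtl_sets = [np.array([], dtype=int) for _ in range(T)]

    g = M @ effects
    lo, hi = config.record_weight_range
    w = rng.uniform(lo, hi, size=n) if hi > lo else np.full(n, lo)
    Lr = np.linalg.cholesky(traits.R)
    e = (rng.standard_normal((n, T)) @ Lr.T) / np.sqrt(w)[:, None]
    mu = np.zeros(T) if config.mu is None else np.asarray(config.mu, float)
    y = mu + g + e
    phen = PhenotypeTable(list(panel.animal_ids), list(traits.trait_names), y, w)
    return phen, SimulationTruth(qtl_sets, effects, g)


def simulate_dataset(config: SimulationConfig):
    """Genotypes, phenotypes and truth for one seeded scenario."""
    rng = np.random.default_rng(config.seed)
    panel = simulate_genotypes(config, rng)
    phen, truth = simulate_effects_and_phenotypes(panel, config, rng)
    return panel, phen, truth


def preset(name: str, seed: int = 0, **overrides) -> SimulationConfig:
    """Ready-made scenarios.

    ``table1``: three dairy-like traits — two highly correlated yield traits
    sharing 80% of their 50 QTL, and a near-independent trait (somatic-cell-
    count-like) sharing 10%.  ``null``: no QTL anywhere.  ``dense``: every SNP
    causal with fully shared architecture (the regime where GWAS weighting is
    expected to be neutral).
    """
    base = dict(seed=seed, traits=table1_trait_model())
    T = 3
    if name == "table1":
        base.update(
            n_qtl_per_trait=50,
            qtl_overlap=np.array([[1.0, 0.8, 0.1],
                                  [0.8, 1.0, 0.1],
                                  [0.1, 0.1, 1.0]]),
        )
    elif name == "null":
        base.update(n_qtl_per_trait=0, qtl_overlap=np.eye(T))
    elif name == "dense":
        base.update(
            n_qtl_per_trait=overrides.get("n_snps", 2000),
            qtl_overlap=np.ones((T, T)),
        )
    else:
        raise ValidationError(f"unknown preset {name!r}")
    base.update(overrides)
    return SimulationConfig(**base)


def write_truth(truth: SimulationTruth, trait_names, snp_map, path) -> None:
    df = snp_map.copy()
    for t, name in enumerate(trait_names):
        df[f"effect_{name}"] = truth.true_effects[:, t]
        df[f"is_qtl_{name}"] = np.isin(
            np.arange(len(snp_map)), truth.qtl_indices[t]
        ).astype(int)
    df.to_csv(path, sep="\t", index=False)
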