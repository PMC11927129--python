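"""End-to-end multitrait GWABLUP estimator and pipeline runner.

:class:`GWABLUP` chains the full workflow behind a scikit-learn fit/predict
surface: bend the trait covariances, centre the genotypes on the training
allele frequencies, transform the phenotypes to canonical traits, run the
per-canonical-trait association scan, convert it into SNP weights, build the
per-SNP prior blocks for the chosen scheme, and solve the augmented
mixed-model equations.  ``predict`` centres new animals' allele counts with
the stored training frequencies and returns ``Z_v b̂``.
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin

from . import __version__
from .canonical import CanonicalTransformer
from .datamodel import (
    GenotypePanel,
    TraitModel,
    ValidationError,
    center_genotypes,
    write_covariance,
    write_genotypes,
    write_phenotypes,
)
from .gwas import single_snp_scan
from .simulate import preset, simulate_dataset, write_truth
from .snpblup import SnpBlup
from .validation import ValidationReport, compare_methods
from .weights import build_prior, build_weight_table, canonical_scheme

logger = logging.getLogger("gwablup")


class GWABLUP(RegressorMixin, BaseEstimator):
    """Multitrait GWAS-weighted SNP-BLUP genomic prediction.

    Parameters
    ----------
    traits : TraitModel
        Trait names with genetic (G) and residual (R) covariances; bent to
        positive definiteness during ``fit``.
    scheme : {"unweighted", "equal_weights", "trait_specific"}
        SNP weighting scheme for the per-SNP prior covariance blocks.
    pi : float, default 0.001
        Prior probability that a SNP has a non-zero effect.
    half_window : int, default 2
        Half-width of the likelihood-ratio moving average (2 → 5-SNP window).
    epsilon : float, default 0.01
        Regularisation of the breeding-value / SNP-effect coupling.
    tolerance, max_iter : PCG stopping rule (relative residual, iteration cap).

    Attributes (after fit)
    ----------------------
    allele_freq_ : training allele frequencies of the retained SNPs
    keep_mask_ : boolean mask of retained (non-monomorphic) SNPs
    canonical_ : fitted :class:`CanonicalTransformer`
    gwas_ : canonical-scale :class:`~gwablup.gwas.GwasResult`
    weight_table_ : :class:`~gwablup.weights.SnpWeightTable` (None if unweighted)
    prior_ : :class:`~gwablup.weights.SnpPrior`
    b_hat_, u_hat_, mu_hat_, n_iter_, converged_ : solver results
    """

    def __init__(
        self,
        traits: TraitModel | None = None,
        scheme: str = "trait_specific",
        pi: float = 0.001,
        half_window: int = 2,
        epsilon: float = 0.01,
        tolerance: float = 1e-9,
        max_iter: int = 20000,
        bend_floor: float = 0.05,
    ):
        self.traits = traits
        self.scheme = scheme
        self.pi = pi
        self.half_window = half_window
        self.epsilon = epsilon
        self.tolerance = tolerance
        self.max_iter = max_iter
        self.bend_floor = bend_floor

    def fit(self, X, y, sample_weight=None, snp_map: pd.DataFrame | None = None):
        """Fit on raw training allele counts X (n, N) and yield deviations
        y (n, T); ``snp_map`` enables chromosome-aware LR smoothing (a single
        chromosome with unit spacing is assumed when omitted)."""
        if self.traits is None:
            raise ValidationError("GWABLUP requires a TraitModel")
        scheme = canonical_scheme(self.scheme)
        X = np.asarray(X, dtype=float)
        y = np.atleast_2d(np.asarray(y, dtype=float))
        n, N = X.shape
        if snp_map is None:
            snp_map = pd.DataFrame({
                "chromosome": ["1"] * N,
                "snp_id": [f"snp{j}" for j in range(N)],
                "position": np.arange(1, N + 1),
            })
        panel = GenotypePanel([f"A{i}" for i in range(n)], snp_map, X)
        centered = center_genotypes(panel)
        w = (np.ones(n) if sample_weight is None
             else np.asarray(sample_weight, float))

        traits = self.traits.bent(self.bend_floor)
        self.traits_ = traits
        self.canonical_ = CanonicalTransformer(G=traits.G, R=traits.R).fit()
        y_canon = self.canonical_.transform(y)

        self.gwas_ = single_snp_scan(centered, y_canon, w)
        if scheme == "unweighted":
            self.weight_table_ = None
        else:
            self.weight_table_ = build_weight_table(
                self.gwas_, self.canonical_, centered.snp_map,
                pi=self.pi, half_window=self.half_window,
                trait_names=list(traits.trait_names),
            )
        self.prior_ = build_prior(
            scheme, traits, centered.scale_sum,
            weight_table=self.weight_table_, n_snps=centered.n_snps,
            epsilon=self.epsilon,
        )
        solver = SnpBlup(
            R=traits.R, prior=self.prior_, epsilon=self.epsilon,
            tolerance=self.tolerance, max_iter=self.max_iter,
        ).fit(centered.matrix, y, sample_weight=w)
        self.solver_ = solver
        self.allele_freq_ = centered.allele_freq
        self.keep_mask_ = np.isin(
            snp_map["snp_id"].to_numpy(), centered.snp_map["snp_id"].to_numpy()
        )
        self.snp_map_ = centered.snp_map
        self.scale_sum_ = centered.scale_sum
        self.mu_hat_ = solver.mu_hat_
        self.u_hat_ = solver.u_hat_
        self.b_hat_ = solver.b_hat_
        self.n_iter_ = solver.n_iter_
        self.rel_residual_ = solver.rel_residual_
        self.converged_ = solver.converged_
        return self

    def _center_new(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.shape[1] == self.keep_mask_.size:
            X = X[:, self.keep_mask_]
        elif X.shape[1] != self.allele_freq_.size:
            raise ValidationError(
                f"panel has {X.shape[1]} SNPs; model was fit on "
                f"{self.keep_mask_.size} ({self.allele_freq_.size} retained)"
            )
        two_p = 2.0 * self.allele_freq_
        return np.where(np.isnan(X), two_p, X) - two_p

    def predict(self, X) -> np.ndarray:
        """Genomic values ``Z_v b̂`` for raw allele counts X, centred with the
        training allele frequencies (monomorphic-in-training SNPs dropped)."""
        return self._center_new(X) @ self.b_hat_


@dataclass
class RunConfig:
    """Configuration of one end-to-end pipeline run."""

    output_dir: Path
    preset_name: str = "table1"
    schemes: tuple[str, ...] = ("unweighted", "equal_weights", "trait_specific")
    pi: float = 0.001
    half_window: int = 2
    epsilon: float = 0.01
    tolerance: float = 1e-9
    max_iter: int = 20000
    n_boot: int = 10000
    seed: int = 0
    sim_overrides: dict = field(default_factory=dict)


def run_pipeline(config: RunConfig) -> ValidationReport:
    """Simulate a scenario, fit every requested scheme on the training
    animals, predict the masked validation animals, and validate.

    All intermediate artifacts (genotypes, map, phenotypes, G, R, truth,
    weight tables, SNP effects, predictions, report, manifest) are persisted
    as TSV/JSON under ``config.output_dir``.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim = preset(config.preset_name, seed=config.seed, **config.sim_overrides)
    panel, phen, truth = simulate_dataset(sim)
    traits = sim.traits
    write_genotypes(panel, out / "genotypes.tsv", out / "snp_map.tsv")
    write_phenotypes(phen, out / "phenotypes.tsv")
    write_covariance(traits.trait_names, traits.G, out / "G.tsv")
    write_covariance(traits.trait_names, traits.R, out / "R.tsv")
    write_truth(truth, traits.trait_names, panel.snp_map, out / "truth.tsv")

    train_ids, valid_ids = sim.training_ids, sim.validation_ids
    train = panel.subset_animals(train_ids)
    valid = panel.subset_animals(valid_ids)
    phen_train = phen.subset_animals(train_ids)
    phen_valid = phen.subset_animals(valid_ids)
    logger.info("training on %d animals, validating on %d (masked)",
                len(train_ids), len(valid_ids))

    predictions: dict[str, np.ndarray] = {}
    for scheme in config.schemes:
        scheme = canonical_scheme(scheme)
        model = GWABLUP(
            traits=traits, scheme=scheme, pi=config.pi,
            half_window=config.half_window, epsilon=config.epsilon,
            tolerance=config.tolerance, max_iter=config.max_iter,
        ).fit(
            train.counts, phen_train.yd,
            sample_weight=phen_train.record_weight, snp_map=train.snp_map,
        )
        logger.info("scheme %s converged=%s in %d iterations (rel res %.2e)",
                    scheme, model.converged_, model.n_iter_,
                    model.rel_residual_)
        predictions[scheme] = model.predict(valid.counts)
        eff = pd.DataFrame(
            model.b_hat_,
            columns=[f"effect_{t}" for t in traits.trait_names],
        )
        eff.insert(0, "snp_id", model.snp_map_["snp_id"].to_numpy())
        eff.to_csv(out / f"snp_effects_{scheme}.tsv", sep="\t", index=False)
        if model.weight_table_ is not None:
            model.weight_table_.to_frame().to_csv(
                out / f"weights_{scheme}.tsv", sep="\t", index=False
            )
        pd.DataFrame(
            predictions[scheme], columns=traits.trait_names
        ).assign(animal_id=valid_ids).to_csv(
            out / f"predictions_{scheme}.tsv", sep="\t", index=False
        )

    report = compare_methods(
        phen_valid.yd, predictions, list(traits.trait_names),
        n_boot=config.n_boot, seed=config.seed,
    ) if len(predictions) > 1 else _single_method_report(
        phen_valid, predictions, traits
    )
    report.to_frame().to_csv(out / "validation_report.tsv", sep="\t",
                             index=False)
    if len(predictions) > 1:
        report.comparisons.to_csv(out / "bootstrap_comparisons.tsv", sep="\t",
                                  index=False)
    manifest = {
        "package_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "seed": config.seed,
        "preset": config.preset_name,
        "schemes": list(config.schemes),
        "pi": config.pi,
        "half_window": config.half_window,
        "epsilon": config.epsilon,
        "tolerance": config.tolerance,
        "n_boot": config.n_boot,
        "n_training": len(train_ids),
        "n_validation": len(valid_ids),
        "sim_overrides": {k: repr(v) for k, v in config.sim_overrides.items()},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return report


def _single_method_report(phen_valid, predictions, traits) -> ValidationReport:
    from .validation import inflation_slope, reliability

    (name, g), = predictions.items()
    T = traits.n_traits
    rel = np.array([[reliability(phen_valid.yd[:, t], g[:, t])
                     for t in range(T)]])
    slp = np.array([[inflation_slope(phen_valid.yd[:, t], g[:, t])
                     for t in range(T)]])
    return ValidationReport(
        list(traits.trait_names), [name], rel, slp, len(phen_valid.animal_ids),
        pd.DataFrame(columns=["method_k", "method_l", "trait",
                              "win_fraction", "significant"]),
    )
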