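# gwablup

Multitrait genomic prediction with GWAS-derived, trait-specific SNP weights
(**GWABLUP**: genome-wide-association-weighted best linear unbiased
prediction).

Standard SNP-BLUP and GBLUP assume every marker contributes equally to the
genetic variance of every trait. When the underlying architecture is sparse —
a modest number of QTL, only partially shared between traits — that
assumption wastes information the data already contain. GWABLUP converts the
association signal of the training data itself into deterministic per-SNP
weights and uses them to rescale each SNP's prior (co)variance inside a
multitrait SNP-BLUP mixed model, mimicking the model averaging of Bayesian
variable-selection predictors at a fraction of their cost. This package
implements the full workflow for T traits — canonical decorrelation, the
association scan, the weighting chain, the augmented mixed-model equations
with their iterative solver, validation statistics, and a synthetic-data
generator for dairy-cattle-like scenarios — behind scikit-learn-style
estimators and a command-line interface. It is written for quantitative
geneticists and animal/plant breeders who want a tested, inspectable
reference implementation at desk scale.

## The model

Phenotypes (yield deviations) of `n` genotyped animals for `T` traits follow

```
y = Xμ + Zb + e,      Z = M ⊗ I_T,      e ~ N(0, W ⊗ R)
```

where `M` is the centred allele-count matrix, `b` the vector of `T·N_snps`
SNP effects, `R` the residual trait covariance, and `W = diag(1/w_i)` the
inverse record weights. Per SNP j the effects are a priori
`b_j ~ N(0, V_SNPj)`; the schemes differ only in `V_SNPj`:

| scheme | per-SNP prior block |
|---|---|
| `unweighted` | `V_SNP = G / Σ_j 2p_j(1−p_j)` |
| `equal_weights` | `V_SNP · PP_j / mean(PP_j)` |
| `trait_specific` | `S_j V_SNP S_j`, `S_j = diag√(PP_tj / meanⱼ PP_tj)` |

The posterior probabilities come from single-SNP scans of the canonically
transformed traits (`Q R Qᵀ = I`, `Q G Qᵀ = diag(λ)`): per SNP and trait the
log-likelihood ratio `LR = ½(b̂/se)²` is smoothed over 5 map-adjacent SNPs
and mapped through `PP = π e^LR / (π e^LR + 1 − π)` with prior `π = 0.001`.
The equal-weights scheme uses one PP from the summed canonical LRs; the
trait-specific scheme back-transforms effects and standard errors to the
original trait scale first, so each trait keeps its own weights while the
prior correlations of `V_SNP` are preserved.

Breeding values `u = Zb` are carried explicitly with a small coupling
regulariser `ε` (default 0.01), giving a three-block symmetric system in
(μ, u, b) that is solved matrix-free by preconditioned conjugate gradients
(block-Jacobi preconditioner, relative-residual tolerance 1e−9). Validation
animals are masked from training and predicted as `ĝ_v = Z_v b̂`; methods are
compared by reliability `cor(y_v, ĝ_v)²`, inflation slope `b(y_v, ĝ_v)`, and
a paired bootstrap over validation animals (significant when one method wins
in > 97.5% of resamples).

## Worked example

Simulate a dairy-like scenario — two yield traits sharing 80% of their 50
QTL and a near-independent somatic-cell-count-like trait — then fit all
three schemes on 1,200 training animals and validate on 300 masked animals:

```python
import gwablup as gw

cfg = gw.preset("table1", seed=7, n_animals=1500, n_validation=300,
                n_snps=1000)
panel, phen, truth = gw.simulate_dataset(cfg)
train, valid = cfg.training_ids, cfg.validation_ids

predictions = {}
for scheme in ("unweighted", "equal_weights", "trait_specific"):
    model = gw.GWABLUP(traits=cfg.traits, scheme=scheme).fit(
        panel.subset_animals(train).counts,
        phen.subset_animals(train).yd, snp_map=panel.snp_map)
    predictions[scheme] = model.predict(panel.subset_animals(valid).counts)

report = gw.compare_methods(phen.subset_animals(valid).yd, predictions,
                            cfg.traits.trait_names, n_boot=10_000, seed=7)
print(report.to_frame().round(3).to_string(index=False))
```

which prints

```
        method   trait  reliability  slope
    unweighted    Milk        0.122  1.161
    unweighted Protein        0.057  0.902
    unweighted     SCC        0.022  0.712
 equal_weights    Milk        0.132  0.952
 equal_weights Protein        0.081  0.772
 equal_weights     SCC        0.062  0.859
trait_specific    Milk        0.151  1.030
trait_specific Protein        0.087  0.792
trait_specific     SCC        0.053  0.710
```

Reliability is the squared correlation between each masked animal's yield
deviation and its genomic prediction: on this replicate the trait-specific
weights lift Milk from 0.122 to 0.151 and Protein from 0.057 to 0.087 over
unweighted SNP-BLUP, and both weighted schemes rescue the near-independent
SCC trait (0.022 → 0.05–0.06); the paired bootstrap flags the SCC
improvements as significant. A slope near 1 means predictions are neither
over- nor under-dispersed. Averages over many replicates (see
`tests/test_acceptance.py`) show the ordering trait_specific ≥ equal_weights
≥ unweighted for the correlated traits, with equal weights — which are
dominated by the yield traits — trailing trait-specific weights on the
near-independent trait.

The same workflow is available from the shell:

```
gwablup run-all --preset table1 --seed 7 --n-animals 1500 \
    --n-validation 300 --n-snps 1000 --out runs/demo
```

## Layout

- `gwablup.datamodel` — genotype/phenotype/covariance containers and TSV IO
- `gwablup.canonical` — covariance bending and the canonical transform
- `gwablup.gwas` — vectorised single-SNP weighted least-squares scans
- `gwablup.weights` — LR smoothing, posterior probabilities, prior blocks
- `gwablup.snpblup` — matrix-free mixed-model equations + PCG (`SnpBlup`)
- `gwablup.pipeline` — the end-to-end `GWABLUP` estimator and pipeline runner
- `gwablup.validation` — reliability, inflation slope, paired bootstrap
- `gwablup.simulate` — LD-structured genotype and sparse-QTL simulator
- `gwablup.cli` — `gwablup` command-line interface

See `docs/methods.md` for modelling assumptions, parameter choices and known
limitations.
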