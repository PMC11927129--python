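# Methods

This note records the model as implemented, the defaults and why they were
chosen, what the synthetic-data generator does and does not emulate, and the
numerical decisions a maintainer would want to know. It states no empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Model and workflow

The prediction model is a multitrait SNP-BLUP: yield deviations
`y = Xμ + Zb + e` with `Z = M ⊗ I_T` for centred allele counts `M`,
residuals `e ~ N(0, W ⊗ R)` with `W = diag(1/w_i)` (an animal with record
weight `w_i` has residual covariance `R / w_i`), and independent per-SNP
prior blocks `b_j ~ N(0, V_SNPj)`. Breeding values `u = Zb` are kept as
explicit unknowns; their joint covariance with `b` is regularised by `ε·I`
so the augmented system

```
[ X'(W⁻¹⊗R⁻¹)X   X'(W⁻¹⊗R⁻¹)          0          ] [μ]   [X'(W⁻¹⊗R⁻¹)y]
[ (W⁻¹⊗R⁻¹)X     (W⁻¹⊗R⁻¹)+I/ε       −Z/ε        ] [u] = [(W⁻¹⊗R⁻¹)y  ]
[ 0              −Z'/ε                Z'Z/ε + Θ⁻¹ ] [b]   [0           ]
```

is non-singular; `Θ = ⊕_j V_SNPj`. `u = Zb` holds only in the `ε → 0`
limit; at the default `ε = 0.01` the relative gap `‖û − Mb̂‖/‖û‖` is of the
order of a few percent at desk scale and shrinks roughly linearly in `ε`
(asserted by the tests). An optional pedigree-weighted variant of the
regulariser (replacing `ε·I` by a pedigree-relationship term) exists in the
literature but is deliberately not implemented here.

The workflow: (1) bend `G` and `R` to positive definiteness; (2) canonically
transform the traits; (3) scan each canonical trait with single-SNP weighted
least squares; (4) turn the scans into per-SNP posterior probabilities and
prior blocks for the chosen scheme; (5) solve the augmented system by PCG;
(6) predict masked animals as `ĝ_v = Z_v b̂` and validate.

## Parameters that matter

| parameter | default | meaning / rationale |
|---|---|---|
| `π` | 0.001 | prior probability of a non-zero SNP effect; at zero evidence PP equals π exactly |
| `half_window` | 2 | LR moving average over 5 map-adjacent SNPs; an LD proxy for the model averaging of MCMC variable-selection methods |
| `ε` | 0.01 | breeding-value/SNP-effect coupling; smaller values tighten `u = Zb` but worsen conditioning |
| `tolerance` | 1e−9 | PCG stopping rule on the true relative residual |
| `bend_floor` (`rel_floor`) | 0.05 | eigenvalue floor for covariance repair, as a fraction of the mean eigenvalue (below) |
| record weights `w_i` | 1 | treated as given input; the residual covariance of animal i is `R/w_i` |

All are unitless except positions (1-based bp in map files).

## Covariance bending

Published trait-correlation tables are rounded and frequently indefinite;
the three-trait dairy parameter set shipped as `table1_trait_model()`
(heritabilities 0.26/0.20/0.16, residual correlations 0.96/−0.17/0.16) has a
residual correlation matrix with a negative eigenvalue (≈ −0.014). Both `G`
and `R` are repaired by eigenvalue clipping. The floor is 5% of the mean
eigenvalue rather than merely positive: with a floor near zero the repaired
`R` keeps an almost noise-free trait combination, whose canonical genetic
variance then explodes (order 10⁴) and dominates every SNP weight. At 5%
the canonical genetic variances of the dairy set come out as
(0.159, 0.247, 1.429), i.e. one low-, one mid- and one high-heritability
canonical trait with environmental variance 1 — a spectrum matching what is
reported for the real (unrounded, positive definite) parameter set. The
clipping floor remains an explicit argument of
`bend_to_positive_definite` for users who want a different repair.

## Canonical transform and back-transformation

`Q` solves the generalized symmetric eigenproblem of the pencil `(G, R)`
(via `scipy.linalg.eigh(G, R)`): `Q R Qᵀ = I`, `Q G Qᵀ = diag(λ)` with λ
ascending; the sign of each row is fixed by making its largest-magnitude
entry positive. Both identities are asserted to 1e−8 on every constructed
transform, and λ is invariant to per-trait rescaling (tested), so assuming
unit phenotypic variances when building `G`/`R` from heritability tables is
harmless. Canonical effect estimates are mapped back per SNP as
`b_orig = Q⁻¹ b_canon` with sampling covariance `Q⁻¹ diag(se²) Q⁻ᵀ`; the
cross-covariances between canonical estimates are taken as zero, which is
exact under the canonical model (independent traits) and an approximation
otherwise.

## Association scan

Each canonical trait is scanned separately — canonical traits are
genetically and environmentally independent, so nothing is lost relative to
a joint scan — with single-SNP weighted least squares (intercept + SNP,
weights `w_i`, per-SNP residual variance on `n − 2` degrees of freedom). No
relationship-matrix correction is applied in the scan; with strong
population structure the LRs would be inflated, which is a known limitation
of the deterministic weighting chain. Degenerate fits (no genotype variance,
or an exact fit) are flagged and enter the weighting at the prior
(`PP = π`) rather than being dropped from the prediction model. Per-SNP
statistics are reduced from contiguous per-column vectors so that scanning
SNP subsets in chunks is bit-identical to one joint scan.

## Weighting chain

`LR = ½(b̂/se)²` per SNP × trait; smoothing averages the LRs of the SNP and
its `half_window` neighbours on each side *within the chromosome* (windows
truncate at chromosome ends, the divisor being the actual window size) —
adjacent-SNP smoothing proxies LD, and LD does not cross chromosomes. The
posterior probability is evaluated directly for moderate LR and through the
logistic form for large LR, so LRs in the thousands cannot overflow; results
are clamped to the open interval (0,1). The combined (equal-weights) PP
smooths each canonical trait's LRs first and then sums them — smoothing and
summation commute for interior SNPs and differ only at chromosome edges —
with the same π. Mean-normalisation of the weights is computed over retained
(post-filter) SNPs, which makes the average per-trait prior variance across
SNPs equal that of the unweighted scheme exactly, so total prior genetic
variance is conserved across schemes; the trait-specific rescaling
`S_j V S_j` leaves every block's correlation structure untouched.

## Solver

The system is applied matrix-free (`Z`, `Z'Z` never materialised; `Θ⁻¹` as
precomputed 3×3 inverses with a PSD guard that adds `1e−10·trace` to blocks
whose smallest eigenvalue is not positive — PP values near zero make blocks
nearly singular). The preconditioner is block-Jacobi: the inverted T×T
diagonal block of each effect level (means, each animal, each SNP), with a
`1e−8·trace/T` diagonal regularisation for singular blocks. Preconditioning
changes only iteration counts, never the solution, so more elaborate
preconditioners would reproduce the same estimates. PCG starts from zero
(runs are bit-reproducible), monitors the recursive residual each iteration,
and recomputes the true residual `rhs − Ax` every 50 iterations (and at any
tentative convergence) to guard against drift; convergence is declared only
on the true relative residual. If rounding breaks conjugacy (true residual
rising an order of magnitude above the best seen), the solver returns the
best iterate with `converged=False` rather than cycling. Weighted schemes
condition the system less well than the unweighted one and take visibly more
iterations, as expected when the prior spectrum spreads over orders of
magnitude.

## Validation

Reliability is `cor(y_v, ĝ_v)²` on masked animals; inflation bias is the
OLS slope of `y_v` on `ĝ_v` (1 = unbiased; < 1 = over-dispersed
predictions). Method pairs are compared by bootstrap over validation
animals: resamples are drawn jointly for `y` and both prediction vectors,
one shared set of resample indices couples all trait/method comparisons in a
run (paired design), correlation ties count as a win for neither method, and
a difference is significant when either method wins > 97.5% of resamples
(two-sided at P < 0.05). Degenerate resamples (constant `y`) are redrawn and
logged. Analytical standard errors of reliabilities are not provided.

## Synthetic data

The generator emulates a dairy-like reference population at desk scale:

* **Genotypes.** Each haplotype is a latent Gaussian AR(1) chain per
  chromosome thresholded at the per-locus allele-frequency quantile, so
  marginal frequencies are exact (drawn uniformly in `allele_freq_range`,
  default 0.05–0.95) and `ld_decay` (default 0.7) directly sets the
  adjacent-marker latent correlation. This is a first-order LD process:
  adequate to exercise frequency computation, centring and the moving-window
  smoothing, but it reproduces neither coalescent LD decay curves, nor
  frequency–effect coupling, nor population structure or relatedness.
* **Architecture.** Each trait gets `n_qtl_per_trait` QTL (default 50);
  pairwise sharing follows the `qtl_overlap` matrix, with shared picks
  preferring SNPs private to the partner trait so other overlaps are not
  inflated. Effects at a QTL shared by traits t and s are drawn with
  correlation `r_ts/overlap_ts`; since the realised genetic correlation is
  bounded by the shared-QTL variance fraction, targets exceeding the overlap
  are rejected with a closed-form feasibility error. Effect columns are then
  rescaled so each trait's realised genetic variance equals `G_tt` exactly
  on the simulated sample.
* **Phenotypes.** `y = μ + M b + e` with `e_i ~ N(0, R/w_i)`; record
  weights default to 1 (complete-record animals), with a range option to
  exercise `W`.
* **Presets.** `table1` — the three-trait dairy setting: heritabilities
  0.26/0.20/0.16, residual correlations 0.96/−0.17/0.16, two yield-like
  traits sharing 80% of their QTL and a near-independent third trait sharing
  10%. Its target milk–protein genetic correlation is 0.80, the upper bound
  attainable under 80% sharing (the published point estimate of 0.85 for the
  real population is unreachable in this architecture without raising the
  overlap, and the architecture is the point of the scenario). `null` — no
  QTL; used for calibration checks. `dense` — every SNP causal with fully
  shared architecture, the regime where GWAS weighting has nothing to find
  and should be neutral.

Consequently, passing tests show that the method behaves as claimed *under
its own assumptions* (sparse partially-shared architectures, homogeneous
unrelated samples, correct `G` and `R`); they do not certify performance on
real livestock data with pedigree structure, selection, imputation error or
misspecified variance components.

## Problem sizes used by the checks

Oracle equivalences (dense direct solves, GBLUP construction) run at
`n ≤ 20` animals, `≤ 30` SNPs, `T = 3`, where dense assembly is exact and
cheap. Calibration of the null statistic uses 5,000 null SNPs on 400
animals. The scheme-ordering study runs 10 seeded replicates of the
`table1` preset at 3,000 training + 500 validation animals and 2,000 SNPs
with 50 QTL per trait — large enough for the GWAS to have real power and
small enough to keep the full suite comfortable on one CPU — and averages
reliabilities and |slope − 1| over replicates before comparing schemes.

## Known limitations

* Record weights are taken as given; how to derive them from reliabilities
  of deregressed proofs is outside scope.
* The scan has no relationship correction; weights inherit any structure
  confounding.
* Missing genotypes are mean-imputed (`2p_j`); no dosage support, no
  X-chromosome rules, no VCF/BED parsing.
* Variance components (`G`, `R`) are inputs, not estimated.
* Single-step extensions (non-genotyped animals) are not implemented.
* The ε-coupling makes `û` and `Mb̂` differ by a few percent at the default;
  use the SNP-effect predictions `Z_v b̂` (as `predict` does) rather than
  mixing the two.
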