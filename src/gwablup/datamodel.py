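"""Core domain types and plain-text readers/writers.

Genotypes are stored as allele counts (0/1/2, ``NaN`` for missing) together
with a SNP map (chromosome, identifier, 1-based bp position).  Phenotypes are
per-animal yield deviations for T traits plus a positive record weight, where
the residual covariance of animal *i* is ``R / w_i``.  The trait (co)variance
structure (genetic ``G``, residual ``R``) lives in :class:`TraitModel`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("gwablup")

MAP_COLUMNS = ("chromosome", "snp_id", "position")


class ParseError(ValueError):
    """A file could not be parsed into a domain type."""


class ValidationError(ValueError):
    """An input violates a documented invariant."""


def _validate_map(snp_map: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in MAP_COLUMNS if c not in snp_map.columns]
    if missing:
        raise ValidationError(f"SNP map lacks required columns: {missing}")
    snp_map = snp_map.reset_index(drop=True)
    pos = snp_map["position"].to_numpy()
    if not np.issubdtype(pos.dtype, np.number):
        raise ValidationError("SNP map positions must be numeric")
    chrom = snp_map["chromosome"].astype(str).to_numpy()
    # strictly increasing position within each chromosome block
    for c in pd.unique(chrom):
        p = pos[chrom == c]
        if np.any(np.diff(p) <= 0):
            raise ValidationError(
                f"SNP map positions not strictly increasing on chromosome {c}"
            )
    return snp_map


@dataclass
class GenotypePanel:
    """Animals × SNPs allele-count matrix plus its SNP map."""

    animal_ids: list[str]
    snp_map: pd.DataFrame
    counts: np.ndarray  # float array; entries in {0,1,2} or NaN (missing)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        self.snp_map = _validate_map(self.snp_map)
        n_a, n_snp = self.counts.shape
        if n_a != len(self.animal_ids):
            raise ValidationError(
                f"{len(self.animal_ids)} animal ids but {n_a} genotype rows"
            )
        if n_snp != len(self.snp_map):
            raise ValidationError(
                f"map length {len(self.snp_map)} != {n_snp} genotype columns"
            )
        observed = self.counts[~np.isnan(self.counts)]
        if observed.size and not np.isin(observed, (0.0, 1.0, 2.0)).all():
            bad = observed[~np.isin(observed, (0.0, 1.0, 2.0))]
            raise ValidationError(f"allele counts outside {{0,1,2}}: {bad[:5]}")

    @property
    def n_animals(self) -> int:
        return self.counts.shape[0]

    @property
    def n_snps(self) -> int:
        return self.counts.shape[1]

    @property
    def snp_ids(self) -> np.ndarray:
        return self.snp_map["snp_id"].to_numpy()

    def subset_animals(self, ids: Sequence[str]) -> "GenotypePanel":
        index = {a: i for i, a in enumerate(self.animal_ids)}
        try:
            rows = [index[a] for a in ids]
        except KeyError as e:
            raise ValidationError(f"animal id not in panel: {e.args[0]}") from None
        return GenotypePanel(list(ids), self.snp_map, self.counts[rows])


@dataclass
class CenteredGenotypes:
    """Centred allele counts with the training allele frequencies that built them.

    ``matrix`` holds ``counts - 2 p_j`` for every animal, where ``p_j`` was
    computed on the reference (training) animals only; ``scale_sum`` is
    ``sum_j 2 p_j (1 - p_j)`` over the retained SNPs.
    """

    matrix: np.ndarray
    allele_freq: np.ndarray
    scale_sum: float
    snp_map: pd.DataFrame
    animal_ids: list[str]
    n_dropped_monomorphic: int = 0
    n_imputed: int = 0

    def __post_init__(self) -> None:
        if not (self.scale_sum > 0):
            raise ValidationError("scale_sum must be positive")
        if np.any(self.allele_freq <= 0) or np.any(self.allele_freq >= 1):
            raise ValidationError("allele frequencies must lie strictly in (0,1)")

    @property
    def n_snps(self) -> int:
        return self.matrix.shape[1]

    def subset_animals(self, ids: Sequence[str]) -> "CenteredGenotypes":
        index = {a: i for i, a in enumerate(self.animal_ids)}
        rows = [index[a] for a in ids]
        return CenteredGenotypes(
            self.matrix[rows], self.allele_freq, self.scale_sum,
            self.snp_map, list(ids),
            self.n_dropped_monomorphic, self.n_imputed,
        )


@dataclass
class PhenotypeTable:
    """Per-animal yield deviations for T traits with positive record weights."""

    animal_ids: list[str]
    trait_names: list[str]
    yd: np.ndarray            # (n_a, T)
    record_weight: np.ndarray  # (n_a,), w_i > 0; Var(e_i) = R / w_i

    def __post_init__(self) -> None:
        self.yd = np.atleast_2d(np.asarray(self.yd, dtype=float))
        self.record_weight = np.asarray(self.record_weight, dtype=float)
        if self.yd.shape != (len(self.animal_ids), len(self.trait_names)):
            raise ValidationError(
                f"yd shape {self.yd.shape} inconsistent with "
                f"{len(self.animal_ids)} animals x {len(self.trait_names)} traits"
            )
        if self.record_weight.shape != (len(self.animal_ids),):
            raise ValidationError("one record weight per animal required")
        if np.any(~np.isfinite(self.yd)):
            raise ValidationError("missing yield deviations are not supported")
        if np.any(self.record_weight <= 0):
            raise ValidationError("record weights must be strictly positive")

    @property
    def n_traits(self) -> int:
        return len(self.trait_names)

    def subset_animals(self, ids: Sequence[str]) -> "PhenotypeTable":
        index = {a: i for i, a in enumerate(self.animal_ids)}
        try:
            rows = [index[a] for a in ids]
        except KeyError as e:
            raise ValidationError(f"animal id not phenotyped: {e.args[0]}") from None
        return PhenotypeTable(
            list(ids), self.trait_names, self.yd[rows], self.record_weight[rows]
        )


def _check_symmetric(S: np.ndarray, name: str) -> np.ndarray:
    S = np.asarray(S, dtype=float)
    if S.ndim != 2 or S.shape[0] != S.shape[1]:
        raise ValidationError(f"{name} must be square, got shape {S.shape}")
    if not np.allclose(S, S.T, atol=1e-8):
        raise ValidationError(f"{name} must be symmetric")
    return 0.5 * (S + S.T)


@dataclass
class TraitModel:
    """Trait names with genetic (G) and residual (R) covariance matrices."""

    trait_names: list[str]
    G: np.ndarray
    R: np.ndarray

    def __post_init__(self) -> None:
        T = len(self.trait_names)
        self.G = _check_symmetric(self.G, "G")
        self.R = _check_symmetric(self.R, "R")
        if self.G.shape != (T, T) or self.R.shape != (T, T):
            raise ValidationError("G and R must be T x T for T trait names")

    @property
    def n_traits(self) -> int:
        return len(self.trait_names)

    @classmethod
    def from_correlations(
        cls,
        trait_names: Sequence[str],
        heritabilities: Sequence[float],
        genetic_corr: np.ndarray,
        residual_corr: np.ndarray,
    ) -> "TraitModel":
        """Build G and R assuming unit phenotypic variance per trait.

        With unit phenotypic variances the genetic variance of trait t equals
        its heritability and the residual variance equals ``1 - h2_t``.
        """
        h2 = np.asarray(heritabilities, dtype=float)
        if np.any(h2 <= 0) or np.any(h2 >= 1):
            raise ValidationError("heritabilities must lie in (0,1)")
        sg = np.sqrt(h2)
        se = np.sqrt(1.0 - h2)
        Cg = _check_symmetric(genetic_corr, "genetic correlation matrix")
        Ce = _check_symmetric(residual_corr, "residual correlation matrix")
        G = np.outer(sg, sg) * Cg
        R = np.outer(se, se) * Ce
        return cls(list(trait_names), G, R)

    def bent(self, rel_floor: float = 0.05) -> "TraitModel":
        """Return a copy with G and R bent to positive definiteness.

        Rounded published correlation tables are frequently indefinite; both
        matrices are repaired by eigenvalue clipping at ``rel_floor`` times
        their mean eigenvalue (see :func:`gwablup.canonical.bend_to_positive_definite`).
        The default floor of 5% keeps the repaired residual covariance away
        from singularity: a merely-positive floor would leave one trait
        combination with essentially no residual variance, handing it an
        unbounded canonical genetic variance and letting it dominate every
        SNP weight.
        """
        from .canonical import bend_to_positive_definite

        floor_G = rel_floor * np.trace(self.G) / self.n_traits
        floor_R = rel_floor * np.trace(self.R) / self.n_traits
        return TraitModel(
            list(self.trait_names),
            bend_to_positive_definite(self.G, floor_G),
            bend_to_positive_definite(self.R, floor_R),
        )


@dataclass
class FitResult:
    """Solution of the augmented mixed-model equations plus solver diagnostics."""

    mu_hat: np.ndarray   # (T,)
    u_hat: np.ndarray    # (n_a, T) breeding values of training animals
    b_hat: np.ndarray    # (N_snps, T) SNP effects
    iterations: int
    rel_residual: float
    converged: bool
    scheme: str
    trait_names: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# plain-text IO
# ---------------------------------------------------------------------------

def load_snp_map(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chromosome": str, "snp_id": str})
    return _validate_map(df)


def write_snp_map(snp_map: pd.DataFrame, path: str | Path) -> None:
    snp_map[list(MAP_COLUMNS)].to_csv(path, sep="\t", index=False)


def load_genotypes(
    path: str | Path,
    map_path: str | Path,
    format: str = "tsv_matrix",
) -> GenotypePanel:
    """Read a genotype panel from a matrix file plus its accompanying map.

    ``tsv_matrix``: header row of snp_ids, then one row per animal of
    ``animal_id<TAB>counts...``.  ``plink_raw_like``: whitespace-separated
    PLINK ``.raw``-style table (FID IID ... then ``<snp>_<allele>`` columns).
    """
    snp_map = load_snp_map(map_path)
    if format == "tsv_matrix":
        df = pd.read_csv(path, sep="\t", dtype={0: str}, na_values=["NA", "."])
        snp_cols = list(df.columns[1:])
        animal_ids = df.iloc[:, 0].astype(str).tolist()
        counts = df[snp_cols].to_numpy(dtype=float)
    elif format == "plink_raw_like":
        df = pd.read_csv(path, sep=r"\s+", na_values=["NA"])
        meta = [c for c in ("FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE")
                if c in df.columns]
        if "IID" not in df.columns:
            raise ParseError("plink_raw_like file lacks an IID column")
        snp_cols = [c for c in df.columns if c not in meta]
        animal_ids = df["IID"].astype(str).tolist()
        counts = df[snp_cols].to_numpy(dtype=float)
        snp_cols = [c.rsplit("_", 1)[0] if "_" in c else c for c in snp_cols]
    else:
        raise ValueError(f"unknown genotype format: {format!r}")
    if list(map(str, snp_cols)) != [str(s) for s in snp_map["snp_id"]]:
        raise ParseError("genotype column order does not match the SNP map")
    return GenotypePanel(animal_ids, snp_map, counts)


def write_genotypes(
    panel: GenotypePanel, path: str | Path, map_path: str | Path
) -> None:
    write_snp_map(panel.snp_map, map_path)
    with open(path, "w") as fh:
        fh.write("animal_id\t" + "\t".join(map(str, panel.snp_ids)) + "\n")
        for aid, row in zip(panel.animal_ids, panel.counts):
            cells = ["NA" if np.isnan(v) else str(int(v)) for v in row]
            fh.write(str(aid) + "\t" + "\t".join(cells) + "\n")


def load_phenotypes(path: str | Path, weight_column: str = "weight") -> PhenotypeTable:
    df = pd.read_csv(path, sep="\t", dtype={"animal_id": str})
    if "animal_id" not in df.columns or weight_column not in df.columns:
        raise ParseError(
            f"phenotype file needs 'animal_id' and '{weight_column}' columns"
        )
    traits = [c for c in df.columns if c not in ("animal_id", weight_column)]
    return PhenotypeTable(
        df["animal_id"].tolist(),
        traits,
        df[traits].to_numpy(dtype=float),
        df[weight_column].to_numpy(dtype=float),
    )


def write_phenotypes(table: PhenotypeTable, path: str | Path) -> None:
    df = pd.DataFrame(table.yd, columns=table.trait_names)
    df.insert(0, "animal_id", table.animal_ids)
    df["weight"] = table.record_weight
    df.to_csv(path, sep="\t", index=False)


def load_covariance(path: str | Path) -> tuple[list[str], np.ndarray]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return list(df.columns), _check_symmetric(df.to_numpy(dtype=float), str(path))


def write_covariance(names: Sequence[str], S: np.ndarray, path: str | Path) -> None:
    pd.DataFrame(S, index=list(names), columns=list(names)).to_csv(path, sep="\t")


def load_trait_model(g_path: str | Path, r_path: str | Path) -> TraitModel:
    names_g, G = load_covariance(g_path)
    names_r, R = load_covariance(r_path)
    if names_g != names_r:
        raise ValidationError("trait names differ between G and R files")
    return TraitModel(names_g, G, R).bent()


# ---------------------------------------------------------------------------
# centering
# ---------------------------------------------------------------------------

def center_genotypes(
    panel: GenotypePanel, reference_ids: Sequence[str] | None = None
) -> CenteredGenotypes:
    """Centre allele counts on training-set allele frequencies.

    ``p_j`` is the allele frequency among ``reference_ids`` (defaults to all
    animals).  Every animal — training and validation alike — is centred as
    ``counts_j - 2 p_j``, so validation genotypes never leak into the
    frequencies.  SNPs monomorphic in the reference are dropped (with a logged
    count); missing genotypes are mean-imputed to ``2 p_j``.
    """
    if reference_ids is None:
        reference_ids = panel.animal_ids
    if len(reference_ids) == 0:
        raise ValidationError("reference_ids must be nonempty")
    index = {a: i for i, a in enumerate(panel.animal_ids)}
    ref_rows = np.array([index[a] for a in reference_ids])

    ref = panel.counts[ref_rows]
    p = np.nanmean(ref, axis=0) / 2.0
    keep = (p > 0.0) & (p < 1.0) & np.isfinite(p)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("dropped %d SNP(s) monomorphic in the reference set", n_dropped)

    counts = panel.counts[:, keep]
    p = p[keep]
    n_missing = int(np.isnan(counts).sum())
    if n_missing:
        logger.info("mean-imputed %d missing genotype(s)", n_missing)
    matrix = np.where(np.isnan(counts), 2.0 * p, counts) - 2.0 * p
    scale_sum = float(np.sum(2.0 * p * (1.0 - p)))
    return CenteredGenotypes(
        matrix=matrix,
        allele_freq=p,
        scale_sum=scale_sum,
        snp_map=panel.snp_map.loc[keep].reset_index(drop=True),
        animal_ids=list(panel.animal_ids),
        n_dropped_monomorphic=n_dropped,
        n_imputed=n_missing,
    )
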