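import numpy as np
import pandas as pd
import pytest

from gwablup import GenotypePanel, PhenotypeTable, TraitModel


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def make_map(n_snps, n_chrom=1):
    sizes = np.full(n_chrom, n_snps // n_chrom)
    sizes[: n_snps % n_chrom] += 1
    chroms, ids, pos = [], [], []
    for c, L in enumerate(sizes, start=1):
        chroms += [str(c)] * L
        ids += [f"snp{c}_{j}" for j in range(L)]
        pos += [100 * (j + 1) for j in range(L)]
    return pd.DataFrame({"chromosome": chroms, "snp_id": ids, "position": pos})


def random_panel(rng, n_animals=8, n_snps=10, n_chrom=2):
    counts = rng.integers(0, 3, size=(n_animals, n_snps)).astype(float)
    # guarantee polymorphism everywhere
    counts[0] = 0
    counts[1] = 1
    counts[2] = 2
    ids = [f"A{i}" for i in range(n_animals)]
    return GenotypePanel(ids, make_map(n_snps, n_chrom), counts)


def random_pd(rng, T, scale=1.0):
    A = rng.standard_normal((T, T + 2))
    return scale * (A @ A.T / (T + 2) + 0.1 * np.eye(T))


@pytest.fixture
def small_panel(rng):
    return random_panel(rng)


@pytest.fixture
def trait_model_2():
    G = np.array([[0.3, 0.1], [0.1, 0.2]])
    R = np.array([[0.7, 0.2], [0.2, 0.8]])
    return TraitModel(["t1", "t2"], G, R)


@pytest.fixture
def tiny_instance(rng, trait_model_2):
    """Small dense-checkable training problem: 6 animals, 8 SNPs, 2 traits."""
    panel = random_panel(rng, n_animals=6, n_snps=8, n_chrom=2)
    w = rng.uniform(0.5, 1.0, size=6)
    Y = rng.standard_normal((6, 2))
    phen = PhenotypeTable(panel.animal_ids, trait_model_2.trait_names, Y, w)
    return panel, phen, trait_model_2
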