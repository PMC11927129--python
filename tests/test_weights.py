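import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gwablup import (
    TraitModel,
    ValidationError,
    base_vsnp,
    build_prior,
    loglik_ratio,
    moving_average_by_chromosome,
    posterior_probability,
)
from gwablup.weights import SnpWeightTable

from conftest import make_map


class TestLoglikRatio:
    def test_forced_arithmetic(self):
        assert loglik_ratio(0.1, 0.05) == pytest.approx(2.0)

    def test_zero_effect(self):
        assert loglik_ratio(0.0, 0.3) == 0.0

    def test_duplicate_arithmetic_oracle(self, rng):
        eff = rng.standard_normal(200)
        se = rng.uniform(0.01, 2.0, size=200)
        expected = np.array([0.5 * b * b / (s * s) for b, s in zip(eff, se)])
        np.testing.assert_allclose(loglik_ratio(eff, se), expected, rtol=1e-14)

    def test_nonpositive_se_rejected(self):
        with pytest.raises(ValidationError):
            loglik_ratio(0.1, 0.0)


class TestMovingAverage:
    def test_forced_arithmetic(self):
        v = np.array([0.0, 0.0, 10.0, 0.0, 0.0])
        out = moving_average_by_chromosome(v, make_map(5), half_window=2)
        assert out[2] == pytest.approx(2.0)

    def test_zero_window_is_identity(self, rng):
        v = rng.uniform(0, 5, size=7)
        out = moving_average_by_chromosome(v, make_map(7), half_window=0)
        np.testing.assert_array_equal(out, v)

    def test_windows_do_not_cross_chromosomes(self):
        v = np.array([0.0, 0.0, 0.0, 9.0, 9.0, 9.0])
        out = moving_average_by_chromosome(v, make_map(6, n_chrom=2),
                                           half_window=2)
        # first element of chromosome 2 averages only chromosome-2 values
        np.testing.assert_allclose(out, [0, 0, 0, 9, 9, 9])

    def test_against_bruteforce_oracle(self, rng):
        snp_map = make_map(23, n_chrom=3)
        v = rng.uniform(0, 4, size=23)
        hw = 2
        chrom = snp_map["chromosome"].to_numpy()
        expected = np.empty(23)
        for j in range(23):
            win = [k for k in range(23)
                   if chrom[k] == chrom[j] and abs(k - j) <= hw]
            expected[j] = np.mean(v[win])
        out = moving_average_by_chromosome(v, snp_map, half_window=hw)
        np.testing.assert_allclose(out, expected, rtol=1e-12)

    def test_column_means_preserved_up_to_boundaries(self, rng):
        # a circular-free average with truncation changes means only through
        # boundary windows; on a constant vector it is exact
        v = np.full(11, 3.3)
        out = moving_average_by_chromosome(v, make_map(11), half_window=2)
        np.testing.assert_allclose(out, v)


class TestPosteriorProbability:
    def test_zero_lr_returns_prior_exactly(self):
        assert posterior_probability(0.0, 0.001) == 0.001

    def test_high_precision_value(self):
        assert posterior_probability(20.0, 0.001) == pytest.approx(
            0.999998, abs=5e-7)

    def test_huge_lr_no_overflow(self):
        pp = posterior_probability(800.0, 0.001)
        assert np.isfinite(pp) and pp < 1.0

    @given(st.floats(min_value=0.0, max_value=700.0),
           st.floats(min_value=1e-6, max_value=0.5))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_matches_direct_formula_and_is_bounded(self, lr, pi):
        pp = posterior_probability(lr, pi)
        direct = pi * np.exp(lr) / (pi * np.exp(lr) + 1 - pi)
        assert 0.0 < pp < 1.0
        assert pp == pytest.approx(direct, rel=1e-9)

    def test_monotone_in_lr(self):
        lrs = np.linspace(0, 100, 400)
        pps = posterior_probability(lrs, 0.001)
        assert np.all(np.diff(pps) >= 0)

    def test_limits(self):
        assert posterior_probability(1e-12, 0.001) == pytest.approx(0.001)
        assert posterior_probability(5000.0, 0.001) > 1 - 1e-12

    def test_bad_pi_rejected(self):
        with pytest.raises(ValidationError):
            posterior_probability(1.0, 0.0)
        with pytest.raises(ValidationError):
            posterior_probability(-0.5, 0.1)


def _weight_table(pp, pp_combined, pi=0.001):
    pp = np.atleast_2d(pp)
    n, T = pp.shape
    lr = np.zeros((n, T))
    return SnpWeightTable(make_map(n), lr, lr, pp,
                          np.asarray(pp_combined, float), pi)


class TestBuildPrior:
    def setup_method(self):
        self.traits = TraitModel(["a", "b"],
                                 np.array([[4.0, 2.0], [2.0, 4.0]]),
                                 np.eye(2))

    def test_base_vsnp(self):
        np.testing.assert_allclose(
            base_vsnp(TraitModel(["a"], np.eye(1), np.eye(1)), 2.0),
            0.5 * np.eye(1))
        # total implied genetic variance over SNPs recovers G
        V = base_vsnp(self.traits, 3.7)
        np.testing.assert_allclose(3.7 * V, self.traits.G)

    def test_unweighted_blocks_identical(self):
        prior = build_prior("unweighted", self.traits, 2.0, n_snps=5)
        assert prior.blocks.shape == (5, 2, 2)
        for b in prior.blocks:
            np.testing.assert_array_equal(b, prior.base_V)

    def test_equal_pp_reduces_weighted_to_unweighted(self):
        wt = _weight_table(np.full((4, 2), 0.25), np.full(4, 0.4))
        for scheme in ("equal_weights", "trait_specific"):
            prior = build_prior(scheme, self.traits, 2.0, weight_table=wt)
            np.testing.assert_allclose(
                prior.blocks, np.broadcast_to(prior.base_V, (4, 2, 2)),
                atol=1e-12)

    def test_trait_specific_forced_arithmetic(self):
        # PP chosen so S_0 = diag(2, 1); then S V S on V = [[4,2],[2,4]]
        # must give [[16,4],[4,4]] and preserve the correlation of 0.5
        pp0 = np.concatenate([[0.8], np.full(7, 0.8 / 7)])  # mean 0.2 -> s=2
        pp1 = np.full(8, 0.3)                               # constant -> s=1
        wt = _weight_table(np.column_stack([pp0, pp1]), np.full(8, 0.5))
        prior = build_prior("trait_specific", self.traits, 1.0,
                            weight_table=wt)
        np.testing.assert_allclose(prior.blocks[0],
                                   [[16.0, 4.0], [4.0, 4.0]], rtol=1e-12)
        corr = prior.blocks[0][0, 1] / np.sqrt(
            prior.blocks[0][0, 0] * prior.blocks[0][1, 1])
        assert corr == pytest.approx(0.5)

    def test_correlations_preserved_per_snp(self, rng):
        pp = rng.uniform(0.001, 0.999, size=(30, 2))
        wt = _weight_table(pp, rng.uniform(0.001, 0.999, size=30))
        prior = build_prior("trait_specific", self.traits, 2.0,
                            weight_table=wt)
        base_corr = prior.base_V[0, 1] / np.sqrt(
            prior.base_V[0, 0] * prior.base_V[1, 1])
        for b in prior.blocks:
            corr = b[0, 1] / np.sqrt(b[0, 0] * b[1, 1])
            assert corr == pytest.approx(base_corr, rel=1e-10)

    def test_mean_block_variance_conserved(self, rng):
        pp = rng.uniform(0.001, 0.999, size=(50, 2))
        wt = _weight_table(pp, rng.uniform(0.001, 0.999, size=50))
        for scheme in ("unweighted", "equal_weights", "trait_specific"):
            prior = build_prior(scheme, self.traits, 2.0, weight_table=wt)
            mean_var = prior.blocks.mean(axis=0)
            np.testing.assert_allclose(np.diag(mean_var),
                                       np.diag(prior.base_V), rtol=1e-10)

    def test_single_trait_equal_weights_equals_trait_specific(self, rng):
        traits1 = TraitModel(["a"], np.array([[0.3]]), np.array([[0.7]]))
        pp = rng.uniform(0.001, 0.999, size=(20, 1))
        wt = _weight_table(pp, pp[:, 0])
        eqw = build_prior("equal_weights", traits1, 2.0, weight_table=wt)
        tsw = build_prior("trait_specific", traits1, 2.0, weight_table=wt)
        np.testing.assert_allclose(eqw.blocks, tsw.blocks, rtol=1e-12)

    def test_weighted_scheme_requires_table(self):
        with pytest.raises(ValidationError):
            build_prior("trait_specific", self.traits, 2.0)

    def test_block_inverses_guard_near_singular(self):
        pp = np.full((3, 2), 1e-300)
        pp[0] = 0.999
        wt = _weight_table(np.clip(pp, np.nextafter(0, 1), None),
                           np.full(3, 0.5))
        prior = build_prior("trait_specific", self.traits, 2.0,
                            weight_table=wt)
        inv = prior.block_inverses()
        assert np.all(np.isfinite(inv))


def test_manhattan_plot_writes_file(tmp_path, rng):
    from gwablup.weights import manhattan_plot

    pp = rng.uniform(0.001, 0.999, size=(30, 2))
    wt = _weight_table(pp, rng.uniform(0.001, 0.999, size=30))
    wt.snp_map = make_map(30, n_chrom=3)
    manhattan_plot(wt, tmp_path / "pp.png")
    assert (tmp_path / "pp.png").stat().st_size > 0
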