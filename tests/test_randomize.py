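"""The four null models: conservation laws, AR(1) fitting, S construction."""

import logging

import numpy as np
import pytest
from scipy import stats
from statsmodels.regression.linear_model import yule_walker

from periodsig.matrix_io import ExpressionMatrix
from periodsig.pipeline import null_score_array
from periodsig.preprocess import RowStandardizer
from periodsig.randomize import (
    cycle_blocks,
    fit_ar1,
    fit_ar1_matrix,
    generate_ar1,
    prefix_mask,
    randomize,
    randomize_A,
    randomize_P,
    randomize_R,
    randomize_S,
    replicate_seed,
)


class TestMethodP:
    def test_global_multiset_conserved_bit_exact(self, small_matrix):
        out = randomize_P(small_matrix, seed=3)
        assert np.array_equal(np.sort(out.values.ravel()),
                              np.sort(small_matrix.values.ravel()))
        assert out.gene_ids == small_matrix.gene_ids

    def test_all_arrangements_equally_likely(self):
        # 2x2 distinct values: each of the 4! arrangements ~ uniform
        # (multinomial goodness of fit across independent seeds)
        m = ExpressionMatrix(["a", "b"], ["t1", "t2"],
                             np.array([[1.0, 2.0], [3.0, 4.0]]))
        counts = {}
        n_rep = 2400
        for r in range(n_rep):
            out = randomize_P(m, seed=r)
            counts[tuple(out.values.ravel())] = \
                counts.get(tuple(out.values.ravel()), 0) + 1
        assert len(counts) == 24
        gof = stats.chisquare(list(counts.values()))
        assert gof.pvalue > 0.001


class TestMethodR:
    def test_constant_row_unchanged(self):
        values = np.array([[7.0, 7.0, 7.0], [1.0, 2.0, 3.0]])
        m = ExpressionMatrix(["a", "b"], ["t1", "t2", "t3"], values)
        out = randomize_R(m, seed=0)
        assert np.array_equal(out.values[0], values[0])

    def test_per_row_multisets_conserved(self, small_matrix):
        out = randomize_R(small_matrix, seed=5)
        assert np.array_equal(np.sort(out.values, axis=1),
                              np.sort(small_matrix.values, axis=1))

    def test_row_moments_preserved(self, small_matrix):
        out = randomize_R(small_matrix, seed=5)
        assert np.allclose(out.values.mean(axis=1),
                           small_matrix.values.mean(axis=1), atol=1e-12)
        assert np.allclose(out.values.var(axis=1),
                           small_matrix.values.var(axis=1), atol=1e-12)


class TestFitAr1:
    def test_long_series_consistency(self):
        rng = np.random.default_rng(0)
        m = 10_000
        x = np.empty(m)
        x[0] = rng.standard_normal()
        for t in range(1, m):
            x[t] = 0.5 * x[t - 1] + rng.standard_normal()
        params = fit_ar1(x)
        assert params.alpha[0] == pytest.approx(0.5, abs=0.02)

    def test_white_noise_alpha_near_zero(self, rng):
        x = rng.standard_normal(2000)
        params = fit_ar1(x)
        assert abs(params.alpha[0]) <= 2 / np.sqrt(2000) * 2

    def test_alternating_series_clamped_with_warning(self, caplog):
        x = np.tile([1.0, -1.0], 2000)
        with caplog.at_level(logging.WARNING):
            params = fit_ar1(x)
        assert params.alpha[0] == pytest.approx(-0.999)
        assert "clamped" in caplog.text

    def test_zero_variance_row_floored(self, caplog):
        with caplog.at_level(logging.WARNING):
            params = fit_ar1(np.zeros(10))
        assert params.alpha[0] == 0.0
        assert params.z_variance[0] == pytest.approx(1e-12)

    def test_vectorized_fit_matches_statsmodels(self, rng):
        X = RowStandardizer().fit_transform(rng.standard_normal((20, 30)))
        batch = fit_ar1_matrix(X, method="mle")
        for g in range(20):
            rho, sigma = yule_walker(X[g], order=1, method="mle")
            assert batch.alpha[g] == pytest.approx(rho[0], abs=1e-10)
            assert batch.z_variance[g] == pytest.approx(sigma ** 2, abs=1e-10)


class TestMethodA:
    def test_generated_rows_match_fitted_autocorrelation(self):
        # one fixed row with alpha ~ 0.6; mean lag-1 autocorrelation of the
        # generated rows (pre-standardization) recovers it
        rng = np.random.default_rng(1)
        m = 300
        x = np.empty(m)
        x[0] = rng.standard_normal()
        for t in range(1, m):
            x[t] = 0.6 * x[t - 1] + rng.standard_normal()
        x = (x - x.mean()) / x.std()
        params = fit_ar1(x)
        gen = generate_ar1(params, m, np.random.default_rng(2), n=500)
        gc = gen - gen.mean(axis=1, keepdims=True)
        lag1 = (gc[:, :-1] * gc[:, 1:]).sum(axis=1) / (gc ** 2).sum(axis=1)
        assert lag1.mean() == pytest.approx(params.alpha[0], abs=0.05)

    def test_on_iid_noise_matches_method_R_scores(self, rng):
        # white-noise input: A's null score distribution ~ R's
        X = RowStandardizer().fit_transform(rng.standard_normal((100, 20)))
        scores_a = null_score_array(X, 2.0, "A", 100, seed=11).ravel()
        scores_r = null_score_array(X, 2.0, "R", 100, seed=12).ravel()
        ks = stats.ks_2samp(scores_a, scores_r)
        assert ks.pvalue > 0.01

    def test_value_multiset_not_conserved(self, standardized_matrix):
        out = randomize_A(standardized_matrix, seed=0)
        assert not np.array_equal(np.sort(out.values.ravel()),
                                  np.sort(standardized_matrix.values.ravel()))

    def test_fixed_seed_reproducible(self, standardized_matrix):
        a = randomize_A(standardized_matrix, seed=9)
        b = randomize_A(standardized_matrix, seed=9)
        assert np.array_equal(a.values, b.values)


class TestMethodS:
    def test_one_cycle_m4_direct_construction(self):
        values = np.array([[1.0, 2.0, 3.0, 4.0], [10.0, 20.0, 30.0, 40.0]])
        m = ExpressionMatrix(["a", "b"], list("wxyz"), values)
        # find a seed whose donor permutation swaps the two rows
        for seed in range(100):
            if np.random.default_rng(seed).permutation(2)[0] == 1:
                break
        out = randomize_S(m, cycles=1.0, seed=seed)
        assert np.array_equal(out.values,
                              np.array([[1.0, 2.0, 30.0, 40.0],
                                        [10.0, 20.0, 3.0, 4.0]]))

    def test_identity_permutation_returns_input(self):
        values = np.arange(8.0).reshape(2, 4)
        m = ExpressionMatrix(["a", "b"], list("wxyz"), values)
        for seed in range(100):
            if np.random.default_rng(seed).permutation(2)[0] == 0:
                break
        out = randomize_S(m, cycles=1.0, seed=seed)
        assert np.array_equal(out.values, values)

    def test_column_multisets_conserved(self, small_matrix):
        out = randomize_S(small_matrix, cycles=2.0, seed=4)
        assert np.array_equal(np.sort(out.values, axis=0),
                              np.sort(small_matrix.values, axis=0))

    def test_prefix_mask_splits_cycles_at_midpoint(self):
        assert np.array_equal(prefix_mask(4, 1.0), [True, True, False, False])
        # odd block: prefix gets the extra sample
        assert np.array_equal(prefix_mask(5, 1.0),
                              [True, True, True, False, False])
        assert np.array_equal(
            prefix_mask(8, 2.0),
            [True, True, False, False, True, True, False, False])

    def test_fractional_cycles_make_partial_final_block(self):
        blocks = cycle_blocks(10, 1.5)
        assert blocks == [(0, 7), (7, 10)]

    def test_short_cycle_block_is_fatal(self):
        with pytest.raises(ValueError, match="fewer than 2 samples"):
            cycle_blocks(6, 5.0)

    def test_single_gene_warns_vacuous_null(self, caplog):
        m = ExpressionMatrix(["a"], list("wxyz"), np.arange(4.0)[None, :])
        with caplog.at_level(logging.WARNING):
            out = randomize_S(m, cycles=1.0, seed=0)
        assert np.array_equal(out.values, m.values)
        assert "vacuous" in caplog.text


class TestDeterminism:
    @pytest.mark.parametrize("method", ["P", "R", "A", "S"])
    def test_same_seed_same_bytes(self, standardized_matrix, method):
        kwargs = {"cycles": 2.0} if method == "S" else {}
        a = randomize(standardized_matrix, method, seed=77, **kwargs)
        b = randomize(standardized_matrix, method, seed=77, **kwargs)
        assert np.array_equal(a.values, b.values)

    def test_replicate_substreams_are_isolated(self):
        s1 = replicate_seed(5, 3)
        s2 = replicate_seed(5, 3)
        assert np.array_equal(
            np.random.default_rng(s1).integers(0, 1 << 30, 4),
            np.random.default_rng(s2).integers(0, 1 << 30, 4),
        )
        assert not np.array_equal(
            np.random.default_rng(replicate_seed(5, 3)).integers(0, 1 << 30, 4),
            np.random.default_rng(replicate_seed(5, 4)).integers(0, 1 << 30, 4),
        )
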