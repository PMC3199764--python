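"""Empirical p-values, BH step-up and the FH threshold, against oracles."""

import numpy as np
import pytest
from scipy import stats

from periodsig.pipeline import null_score_array
from periodsig.preprocess import RowStandardizer
from periodsig.score import ScoreTable
from periodsig.significance import (
    bh_adjust,
    compare_procedures,
    empirical_pvalues,
    empirical_pvalues_from_null,
    fh_threshold,
)

# ---------------------------------------------------------------------------
# independent oracles (textbook definitions, deliberately naive)
# ---------------------------------------------------------------------------

def oracle_pvalues_per_gene(scores, null):
    R, n = null.shape
    out = np.empty(n)
    for g in range(n):
        count = 0
        for r in range(R):
            if null[r, g] >= scores[g]:
                count += 1
        out[g] = (1 + count) / (R + 1)
    return out


def oracle_pvalues_pooled(scores, null):
    R, n = null.shape
    flat = null.ravel()
    out = np.empty(n)
    for g in range(n):
        count = sum(1 for v in flat if v >= scores[g])
        out[g] = (1 + count) / (flat.size + 1)
    return out


def oracle_bh(p, q):
    n = len(p)
    order = np.argsort(p, kind="mergesort")
    q_sorted = np.empty(n)
    running = 1.0
    for rank in range(n, 0, -1):
        running = min(running, n * p[order[rank - 1]] / rank)
        q_sorted[rank - 1] = running
    q_values = np.empty(n)
    q_values[order] = q_sorted
    return q_values, q_values <= q


def oracle_fh(orig, null, q):
    R = null.shape[0]
    best = np.inf
    for f in orig:
        n_orig = sum(1 for v in orig if v >= f)
        n_null = sum(1 for v in null.ravel() if v >= f)
        if (n_null / R) / n_orig <= q and f < best:
            best = f
    return best


def tables(orig, null):
    genes = [f"g{i}" for i in range(len(orig))]
    original = ScoreTable(genes, orig, 2.0)
    reps = [ScoreTable(genes, row, 2.0) for row in null]
    return original, reps


# ---------------------------------------------------------------------------
# empirical p-values
# ---------------------------------------------------------------------------

class TestEmpiricalPvalues:
    def test_score_above_all_nulls(self):
        null = np.zeros((99, 1))
        p = empirical_pvalues_from_null(np.array([5.0]), null)
        assert p[0] == pytest.approx(0.01)

    def test_all_ties_give_p_one(self):
        null = np.full((10, 1), 3.0)
        p = empirical_pvalues_from_null(np.array([3.0]), null)
        assert p[0] == 1.0

    def test_lower_bound_is_one_over_R_plus_one(self, rng):
        null = rng.standard_normal((20, 5))
        p = empirical_pvalues_from_null(np.full(5, 1e9), null)
        assert np.all(p == 1 / 21)

    @pytest.mark.parametrize("mode,oracle", [
        ("per_gene", oracle_pvalues_per_gene),
        ("pooled", oracle_pvalues_pooled),
    ])
    def test_matches_brute_force(self, rng, mode, oracle):
        for _ in range(30):
            n, R = 5, 20
            scores = rng.standard_normal(n) ** 2
            null = rng.standard_normal((R, n)) ** 2
            got = empirical_pvalues_from_null(scores, null, mode)
            assert np.allclose(got, oracle(scores, null))

    def test_misaligned_genes_rejected(self, rng):
        orig, reps = tables(rng.random(4), rng.random((2, 4)))
        reps[1].gene_ids = ["x0", "x1", "x2", "x3"]
        with pytest.raises(ValueError, match="align"):
            empirical_pvalues(orig, reps)

    def test_type_one_error_uniform_p_under_matched_null(self):
        # iid noise scored against method R: p-values uniform on the grid
        rng = np.random.default_rng(42)
        n, m, R = 2000, 24, 199
        X = RowStandardizer().fit_transform(rng.standard_normal((n, m)))
        from periodsig.score import score_rows
        scores = score_rows(X, 2.0)
        null = null_score_array(X, 2.0, "R", R, seed=1)
        p = empirical_pvalues_from_null(scores, null, "per_gene")
        counts, _ = np.histogram(p, bins=np.linspace(0, 1, 21))
        gof = stats.chisquare(counts)
        assert gof.pvalue > 0.01


# ---------------------------------------------------------------------------
# Benjamini-Hochberg
# ---------------------------------------------------------------------------

class TestBhAdjust:
    def test_hand_computed_example(self):
        q, sig = bh_adjust(np.array([0.01, 0.02, 0.03, 0.8]), 0.05)
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.8])
        assert list(sig) == [True, True, True, False]

    def test_all_ones(self):
        q, sig = bh_adjust(np.ones(5), 0.05)
        assert np.all(q == 1.0)
        assert not sig.any()

    def test_matches_textbook_oracle_on_random_vectors(self, rng):
        for _ in range(1000):
            n = rng.integers(1, 40)
            p = rng.random(n).clip(1e-12, 1.0)
            q_got, sig_got = bh_adjust(p, 0.1)
            q_exp, sig_exp = oracle_bh(p, 0.1)
            assert np.allclose(q_got, q_exp)
            assert np.array_equal(sig_got, sig_exp)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust(np.array([0.0, 0.5]))
        with pytest.raises(ValueError):
            bh_adjust(np.array([0.5, 1.5]))


# ---------------------------------------------------------------------------
# Futschik-Herzel threshold
# ---------------------------------------------------------------------------

class TestFhThreshold:
    def test_separated_distributions_select_everything(self, rng):
        orig, reps = tables(np.array([2.0, 3.0, 4.0]), np.zeros((3, 3)))
        curve = fh_threshold(orig, reps, 0.05)
        assert curve.selected_f == 2.0
        assert curve.significant(orig.scores).all()
        assert np.allclose(curve.fh_values, 0.0)

    def test_null_equals_original_blocks_selection(self, rng):
        scores = np.arange(1.0, 11.0)
        orig, reps = tables(scores, scores[None, :])
        curve = fh_threshold(orig, reps, 0.05)
        # at every threshold below the max, FH ~ 1; only the top can pass
        assert curve.selected_f >= scores.max()

    def test_hand_enumerated_example(self):
        orig, reps = tables(np.array([5.0, 4.0, 3.0, 1.0]),
                            np.array([[2.0, 1.0, 1.0, 1.0]]))
        curve = fh_threshold(orig, reps, 0.3)
        assert curve.selected_f == 3.0
        assert curve.significant(orig.scores).sum() == 3

    def test_no_qualifying_threshold_gives_zero_significants(self):
        orig, reps = tables(np.array([1.0, 1.0]), np.array([[5.0, 6.0]]))
        curve = fh_threshold(orig, reps, 0.05)
        assert curve.selected_f == np.inf
        assert not curve.significant(orig.scores).any()

    def test_matches_brute_force_on_random_instances(self, rng):
        for _ in range(200):
            n = int(rng.integers(2, 15))
            R = int(rng.integers(1, 5))
            orig_scores = rng.random(n) * 5
            null_scores = rng.random((R, n)) * 5
            orig, reps = tables(orig_scores, null_scores)
            curve = fh_threshold(orig, reps, 0.25)
            assert curve.selected_f == oracle_fh(orig_scores, null_scores, 0.25)


class TestCompareProcedures:
    def test_separated_data_identical_calls(self, rng):
        orig, reps = tables(np.array([5.0, 6.0, 0.1, 0.2]),
                            rng.random((50, 4)) * 0.5)
        report = compare_procedures(orig, reps, 0.05)
        assert report["n_symmetric_difference"] == 0
        assert report["n_bh"] == report["n_fh"] == 2
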