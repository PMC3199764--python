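"""End-to-end periodicity significance testing.

Fixed order of operations, applied identically to original and randomized
data: impute missing values, standardize rows, score.  Randomized matrices
are generated from the preprocessed original and re-standardized before
scoring (cheap for P/R/S, required for A).

:class:`PeriodicityTest` packages the whole procedure as a scikit-learn
style estimator; :func:`periodicity_test` is the functional equivalent.
"""

from __future__ import annotations

import dataclasses
from typing import Any

import numpy as np
from sklearn.base import BaseEstimator

from .matrix_io import ExpressionMatrix
from .preprocess import NormalizationConfig, RowStandardizer, preprocess
from .randomize import fit_ar1_matrix, randomize_values, rng_for_replicate
from .score import CycleSpec, ScoreTable, detect_cycle_count, score_rows
from .significance import (
    FHCurve,
    SignificanceTable,
    bh_adjust,
    empirical_pvalues_from_null,
    fh_threshold,
)


def null_score_array(
    values: np.ndarray,
    cycles: float,
    method: str,
    replicates: int,
    seed: int,
    restandardize: bool = True,
) -> np.ndarray:
    """(replicates, n) periodicity scores of randomized copies of ``values``.

    ``values`` must already be preprocessed; each replicate draws from an
    isolated RNG substream, is re-standardized (the shared normalization
    pipeline) and scored at the same frequency as the original.
    """
    values = np.asarray(values, dtype=float)
    ar_params = fit_ar1_matrix(values) if method == "A" else None
    standardizer = RowStandardizer()
    out = np.empty((replicates, values.shape[0]))
    for r in range(replicates):
        rng = rng_for_replicate(seed, r)
        if method == "identity":  # debug null: no randomization at all
            out[r] = score_rows(values, cycles)
            continue
        rand = randomize_values(values, method, rng, cycles=cycles,
                                ar_params=ar_params, standardize_a=False)
        if restandardize:
            rand = standardizer.fit_transform(rand)
        out[r] = score_rows(rand, cycles)
    return out


@dataclasses.dataclass
class PeriodicityResult:
    """Everything one run of the significance pipeline produced."""

    table: SignificanceTable
    cycle_spec: CycleSpec
    original_scores: ScoreTable
    null_scores: np.ndarray          # (R, n)
    fh_curve: FHCurve | None = None

    @property
    def n_significant(self) -> int:
        return self.table.n_significant


def periodicity_test(
    matrix: ExpressionMatrix,
    cycles: float,
    method: str = "S",
    replicates: int = 1000,
    q_target: float = 0.05,
    procedure: str = "bh",
    mode: str = "per_gene",
    seed: int = 0,
    detect_cycles: bool = False,
    resolution: float = 0.01,
    normalization: NormalizationConfig | None = None,
) -> PeriodicityResult:
    """Impute, standardize, (optionally) detect cycles, score, randomize, call.

    ``procedure`` is ``"bh"`` (Benjamini-Hochberg on empirical p-values) or
    ``"fh"`` (Futschik-Herzel threshold on raw scores).  With
    ``detect_cycles`` the effective cycle count c_adj is grid-searched in
    (0, 2*cycles] and used everywhere downstream, including the S split.
    """
    if procedure not in ("bh", "fh"):
        raise ValueError("procedure must be 'bh' or 'fh'")
    pre = preprocess(matrix, normalization)
    if detect_cycles:
        spec = detect_cycle_count(pre, cycles, resolution)
    else:
        spec = CycleSpec(c_reported=float(cycles))
    use_cycles = spec.cycles
    scores = score_rows(pre.values, use_cycles)
    original = ScoreTable(list(pre.gene_ids), scores, use_cycles)
    null = null_score_array(pre.values, use_cycles, method, replicates, seed)
    provenance: dict[str, Any] = {
        "method": method, "R": replicates, "seed": seed, "mode": mode,
        "cycles": use_cycles, "q_target": q_target,
    }
    fh_curve = None
    if procedure == "bh":
        p = empirical_pvalues_from_null(scores, null, mode)
        qv, sig = bh_adjust(p, q_target)
        provenance["fdr_procedure"] = "benjamini_hochberg"
    else:
        reps = [ScoreTable(list(pre.gene_ids), null[r], use_cycles)
                for r in range(replicates)]
        fh_curve = fh_threshold(original, reps, q_target)
        p = empirical_pvalues_from_null(scores, null, "pooled")
        qv = p
        sig = fh_curve.significant(scores)
        provenance["fdr_procedure"] = "futschik_herzel"
        provenance["selected_f"] = fh_curve.selected_f
    table = SignificanceTable(list(pre.gene_ids), scores, p, qv, sig,
                              provenance)
    return PeriodicityResult(table, spec, original, null, fh_curve)


class PeriodicityTest(BaseEstimator):
    """Periodicity significance test as a fit-shaped estimator.

    ``X`` is an (n_genes, m_timepoints) array or :class:`ExpressionMatrix`;
    genes are the samples.  After ``fit``, per-gene results live in
    ``scores_``, ``p_values_``, ``q_values_`` and ``significant_``;
    ``fit_predict`` returns the boolean significance calls.

    Parameters mirror :func:`periodicity_test`; ``random_state`` seeds all
    randomization replicates.
    """

    def __init__(
        self,
        cycles: float = 2.0,
        method: str = "S",
        replicates: int = 1000,
        q_target: float = 0.05,
        procedure: str = "bh",
        mode: str = "per_gene",
        detect_cycles: bool = False,
        resolution: float = 0.01,
        knn_k: int = 10,
        random_state: int = 0,
    ):
        self.cycles = cycles
        self.method = method
        self.replicates = replicates
        self.q_target = q_target
        self.procedure = procedure
        self.mode = mode
        self.detect_cycles = detect_cycles
        self.resolution = resolution
        self.knn_k = knn_k
        self.random_state = random_state

    def _as_matrix(self, X) -> ExpressionMatrix:
        if isinstance(X, ExpressionMatrix):
            return X
        X = np.asarray(X, dtype=float)
        n, m = X.shape
        return ExpressionMatrix(
            [f"gene_{i + 1}" for i in range(n)],
            [f"t{j}" for j in range(1, m + 1)], X,
        )

    def fit(self, X, y=None):
        matrix = self._as_matrix(X)
        knn_k = min(self.knn_k, max(1, matrix.n_genes - 1))
        result = periodicity_test(
            matrix,
            cycles=self.cycles,
            method=self.method,
            replicates=self.replicates,
            q_target=self.q_target,
            procedure=self.procedure,
            mode=self.mode,
            seed=self.random_state,
            detect_cycles=self.detect_cycles,
            resolution=self.resolution,
            normalization=NormalizationConfig(knn_k=knn_k),
        )
        self.result_ = result
        self.scores_ = result.table.scores
        self.p_values_ = result.table.p_values
        self.q_values_ = result.table.q_values
        self.significant_ = result.table.significant
        self.cycle_spec_ = result.cycle_spec
        self.n_features_in_ = matrix.n_timepoints
        return self

    def fit_predict(self, X, y=None) -> np.ndarray:
        return self.fit(X).significant_
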