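"""Evaluation designs: threshold-fraction experiment and PPV benchmarking.

The threshold-fraction experiment asks how a null model redistributes the
top of the score distribution: pick score thresholds ``delta_s`` so that a
fraction ``s`` of the original genes score strictly above, generate many
randomized datasets, and report the fraction of randomized rows above each
threshold.  A null that reproduces the original score distribution reports
~``s``; a null that compares periodic data against noise reports ~0.

PPV (positive predictive value) compares a significant-gene set against a
benchmark list: PPV = TP / (TP + FP), suppressed when there are fewer than
10 positives (the ratio is not robust there).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .matrix_io import ExpressionMatrix
from .pipeline import null_score_array
from .preprocess import NormalizationConfig, preprocess
from .score import score_rows

DEFAULT_S_LEVELS = (0.05, 0.10, 0.20)

MIN_POSITIVES_FOR_PPV = 10


def delta_threshold(scores: np.ndarray, s: float) -> float:
    """Score threshold with a fraction ~s of genes strictly above.

    Returns the (k+1)-th largest score with ``k = floor(s * n)``, so the
    count strictly above is the largest achievable value <= s*n (ties can
    only lower it, never raise it).
    """
    if not 0 < s < 1:
        raise ValueError("s must lie in (0, 1)")
    scores = np.sort(np.asarray(scores, dtype=float))[::-1]
    k = int(np.floor(s * scores.size + 1e-9))
    if k >= scores.size:
        k = scores.size - 1
    return float(scores[k])


def fraction_above_threshold(
    matrix: ExpressionMatrix,
    method: str,
    cycles: float,
    s_levels: tuple[float, ...] = DEFAULT_S_LEVELS,
    replicates: int = 100,
    seed: int = 0,
    normalization: NormalizationConfig | None = None,
) -> pd.DataFrame:
    """Fraction of randomized rows scoring above each delta_s threshold.

    Thresholds come from the preprocessed original matrix; the reported
    fraction pools all ``n * replicates`` randomized rows, with the
    per-replicate spread alongside.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    pre = preprocess(matrix, normalization)
    original = score_rows(pre.values, cycles)
    null = null_score_array(pre.values, cycles, method, replicates, seed)
    rows = []
    for s in s_levels:
        delta = delta_threshold(original, s)
        above = null > delta
        per_rep = above.mean(axis=1)
        rows.append({
            "s": s,
            "delta": delta,
            "method": method,
            "fraction": float(above.mean()),
            "per_replicate_sd": float(per_rep.std(ddof=1)) if replicates > 1
            else np.nan,
            "n_rows": int(above.size),
        })
    return pd.DataFrame(rows)


@dataclasses.dataclass
class BenchmarkEval:
    """TP/FP counts and the (possibly suppressed) PPV."""

    tp: int
    fp: int
    n_positive: int

    @property
    def ppv(self) -> float | None:
        """TP / (TP + FP); None when there are fewer than 10 positives."""
        if self.n_positive < MIN_POSITIVES_FOR_PPV:
            return None
        return self.tp / (self.tp + self.fp)


def ppv_eval(significant_genes: set[str], benchmark: set[str]) -> BenchmarkEval:
    """Evaluate a significant-gene set against a benchmark ID list.

    No identifier mapping or aliasing is attempted; matching IDs is the
    caller's responsibility.
    """
    significant_genes = set(significant_genes)
    benchmark = set(benchmark)
    tp = len(significant_genes & benchmark)
    fp = len(significant_genes - benchmark)
    return BenchmarkEval(tp=tp, fp=fp, n_positive=len(significant_genes))


def false_discovery_proportion(
    significant: np.ndarray, truth: np.ndarray
) -> float:
    """Realized FDP of boolean calls against boolean truth (0 if no calls)."""
    significant = np.asarray(significant, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    n_called = int(significant.sum())
    if n_called == 0:
        return 0.0
    return float((significant & ~truth).sum() / n_called)
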