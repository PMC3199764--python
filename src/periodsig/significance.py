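"""Empirical p-values and FDR control for periodicity scores.

A gene's empirical one-tailed p-value compares its score against the null
scores from ``R`` randomized matrices with add-one smoothing::

    p(g) = (1 + #{r : F(g, r) >= F(g)}) / (R + 1)

so p is never 0 (required for valid Benjamini-Hochberg input) and ties count
against significance.  ``per_gene`` mode counts only row g's null scores
(the default); ``pooled`` mode counts over all n*R null scores with
denominator n*R + 1 (appropriate when the null makes rows exchangeable, as
under methods P and S).

Two FDR procedures are provided: Benjamini-Hochberg step-up on the empirical
p-values, and the Futschik-Herzel empirical-FDR threshold on the raw scores::

    FH(f) = ( #{(g, r) : F(g, r) >= f} / R ) / #{g : F(g) >= f}

evaluated at every observed original score; the selected threshold is the
smallest observed score with FH(f) <= q (FH is a step function, so the
crossing replaces exact equality).
"""

from __future__ import annotations

import dataclasses
from typing import Any, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .score import ScoreTable

MODES = ("per_gene", "pooled")


@dataclasses.dataclass
class SignificanceTable:
    """Per-gene scores, p-values, q-values and significance calls."""

    gene_ids: list[str]
    scores: np.ndarray
    p_values: np.ndarray
    q_values: np.ndarray
    significant: np.ndarray
    provenance: dict[str, Any] = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.gene_ids)
        self.scores = np.asarray(self.scores, dtype=float)
        self.p_values = np.asarray(self.p_values, dtype=float)
        self.q_values = np.asarray(self.q_values, dtype=float)
        self.significant = np.asarray(self.significant, dtype=bool)
        for arr in (self.scores, self.p_values, self.q_values, self.significant):
            if arr.shape != (n,):
                raise ValueError("all columns must align with the gene list")
        if ((self.p_values <= 0) | (self.p_values > 1)).any():
            raise ValueError("p-values must lie in (0, 1]")

    @property
    def n_significant(self) -> int:
        return int(self.significant.sum())

    def significant_genes(self) -> set[str]:
        return {g for g, s in zip(self.gene_ids, self.significant) if s}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": self.gene_ids,
                "score": self.scores,
                "p_value": self.p_values,
                "q_value": self.q_values,
                "significant": self.significant,
            }
        )


@dataclasses.dataclass
class FHCurve:
    """Futschik-Herzel empirical-FDR curve and the selected threshold."""

    thresholds: np.ndarray      # descending observed original scores
    fh_values: np.ndarray       # FH(f) at each threshold
    selected_f: float           # +inf when no threshold reaches q_target
    q_target: float

    def significant(self, scores: np.ndarray) -> np.ndarray:
        return np.asarray(scores, dtype=float) >= self.selected_f


def _null_matrix(
    original: ScoreTable, randomized: Sequence[ScoreTable]
) -> np.ndarray:
    """Stack aligned replicate score tables into an (R, n) array."""
    if len(randomized) < 1:
        raise ValueError("at least one randomized score table is required")
    for rep in randomized:
        if rep.gene_ids != original.gene_ids:
            raise ValueError("randomized tables must align gene-wise with "
                             "the original")
    return np.stack([rep.scores for rep in randomized], axis=0)


def empirical_pvalues_from_null(
    scores: np.ndarray, null_scores: np.ndarray, mode: str = "per_gene"
) -> np.ndarray:
    """Add-one empirical p-values from an (R, n) null score array."""
    scores = np.asarray(scores, dtype=float)
    null_scores = np.asarray(null_scores, dtype=float)
    R, n = null_scores.shape
    if scores.shape != (n,):
        raise ValueError("scores and null_scores disagree on gene count")
    if mode == "per_gene":
        exceed = (null_scores >= scores[None, :]).sum(axis=0)
        return (1.0 + exceed) / (R + 1.0)
    if mode == "pooled":
        pool = np.sort(null_scores.ravel())
        # count of pooled null scores >= each observed score
        exceed = pool.size - np.searchsorted(pool, scores, side="left")
        return (1.0 + exceed) / (pool.size + 1.0)
    raise ValueError(f"mode must be one of {MODES}")


def empirical_pvalues(
    original: ScoreTable,
    randomized: Sequence[ScoreTable],
    mode: str = "per_gene",
    q_target: float = 0.05,
    provenance: dict[str, Any] | None = None,
) -> SignificanceTable:
    """Empirical p-values plus BH adjustment for aligned score tables."""
    null_scores = _null_matrix(original, randomized)
    p = empirical_pvalues_from_null(original.scores, null_scores, mode)
    q, sig = bh_adjust(p, q_target)
    prov = {
        "fdr_procedure": "benjamini_hochberg",
        "mode": mode,
        "R": null_scores.shape[0],
        "q_target": q_target,
    }
    prov.update(provenance or {})
    return SignificanceTable(list(original.gene_ids), original.scores, p, q,
                             sig, prov)


def bh_adjust(
    p_values: np.ndarray, q_target: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: q-values and significance calls.

    Standard step-up: sort p ascending, q_(i) = min_{j>=i} n*p_(j)/j capped
    at 1, significant where q <= q_target, original order restored.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be a 1-D vector")
    if ((p <= 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in (0, 1]")
    reject, q, _, _ = multipletests(p, alpha=q_target, method="fdr_bh")
    return q, reject


def fh_threshold(
    original: ScoreTable,
    randomized: Sequence[ScoreTable],
    q_target: float = 0.05,
) -> FHCurve:
    """Futschik-Herzel empirical-FDR threshold selection.

    FH is evaluated exactly at the set of observed original scores; the
    selected threshold is the smallest observed score whose FH value is at
    most ``q_target`` (+inf, and zero significant genes, when none
    qualifies).
    """
    if not 0 < q_target < 1:
        raise ValueError("q_target must lie in (0, 1)")
    null_scores = _null_matrix(original, randomized)
    R = null_scores.shape[0]
    thresholds = np.unique(original.scores)[::-1]  # descending
    orig_sorted = np.sort(original.scores)
    null_sorted = np.sort(null_scores.ravel())
    n_orig_ge = original.scores.size - np.searchsorted(
        orig_sorted, thresholds, side="left"
    )
    n_null_ge = null_sorted.size - np.searchsorted(
        null_sorted, thresholds, side="left"
    )
    fh = (n_null_ge / R) / n_orig_ge
    qualifying = thresholds[fh <= q_target]
    selected_f = float(qualifying.min()) if qualifying.size else np.inf
    return FHCurve(thresholds, fh, selected_f, q_target)


def fh_significance(
    original: ScoreTable,
    randomized: Sequence[ScoreTable],
    q_target: float = 0.05,
    provenance: dict[str, Any] | None = None,
) -> tuple[SignificanceTable, FHCurve]:
    """FH threshold calls packaged as a SignificanceTable.

    p- and q-value columns are filled with pooled empirical p-values for
    reference; the significance calls come from the FH threshold.
    """
    curve = fh_threshold(original, randomized, q_target)
    null_scores = _null_matrix(original, randomized)
    p = empirical_pvalues_from_null(original.scores, null_scores, "pooled")
    sig = curve.significant(original.scores)
    prov = {
        "fdr_procedure": "futschik_herzel",
        "R": null_scores.shape[0],
        "q_target": q_target,
        "selected_f": curve.selected_f,
    }
    prov.update(provenance or {})
    return (
        SignificanceTable(list(original.gene_ids), original.scores, p, p, sig,
                          prov),
        curve,
    )


def compare_procedures(
    original: ScoreTable,
    randomized: Sequence[ScoreTable],
    q_target: float = 0.05,
    mode: str = "per_gene",
) -> dict[str, Any]:
    """Run BH and FH on identical inputs and report their (dis)agreement."""
    bh_table = empirical_pvalues(original, randomized, mode=mode,
                                 q_target=q_target)
    fh_table, curve = fh_significance(original, randomized, q_target=q_target)
    bh_set = bh_table.significant_genes()
    fh_set = fh_table.significant_genes()
    sym = bh_set ^ fh_set
    union = bh_set | fh_set
    return {
        "bh_significant": bh_set,
        "fh_significant": fh_set,
        "symmetric_difference": sym,
        "n_bh": len(bh_set),
        "n_fh": len(fh_set),
        "n_symmetric_difference": len(sym),
        "n_union": len(union),
        "fh_curve": curve,
    }
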