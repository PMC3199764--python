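"""Randomization null models P, R, A and S for expression matrices.

Each method generates surrogate matrices that share chosen properties with
the original while destroying experiment-wide periodic structure:

P
    permutes all ``n*m`` entries of the matrix (conserves the global value
    multiset).
R
    permutes the values within each row independently (conserves every row
    multiset).
A
    fits a per-gene AR(1) process ``X_t = alpha * X_{t-1} + Z_t`` by
    Yule-Walker and resamples rows parametrically (conserves autocorrelation
    and innovation variance, not the value multiset; generated rows are
    re-standardized because the model preserves only the innovation
    variance).
S
    splits every gene cycle into a prefix (first half) and a suffix (second
    half) along the time axis, then recombines: row ``g`` keeps its own
    prefixes and takes the suffixes of row ``h(g)``, where ``h`` is one
    uniform permutation of the genes drawn without replacement (conserves
    every column multiset and the within-prefix / within-suffix column
    correlations).

All randomness flows from a single integer seed; replicate ``r`` of a run
draws from an isolated substream so it is reproducible on its own.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
from statsmodels.regression.linear_model import yule_walker

from .matrix_io import ExpressionMatrix
from .preprocess import RowStandardizer

logger = logging.getLogger(__name__)

METHODS = ("P", "R", "A", "S")

ALPHA_CLAMP = 0.999
Z_VARIANCE_FLOOR = 1e-12


@dataclasses.dataclass
class ARParams:
    """Per-gene AR(1) parameters: lag-1 coefficient and innovation variance."""

    alpha: np.ndarray
    z_variance: np.ndarray

    def __post_init__(self) -> None:
        self.alpha = np.atleast_1d(np.asarray(self.alpha, dtype=float))
        self.z_variance = np.atleast_1d(np.asarray(self.z_variance, dtype=float))
        if (np.abs(self.alpha) >= 1).any():
            raise ValueError("|alpha| must be < 1")
        if (self.z_variance <= 0).any():
            raise ValueError("z_variance must be positive")


@dataclasses.dataclass
class RandomizationRun:
    """Reproducible description of a randomization batch."""

    method: str
    replicates: int
    seed: int
    cycles: float | None = None

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")

    @property
    def per_replicate_seeds(self) -> list[np.random.SeedSequence]:
        return [replicate_seed(self.seed, r) for r in range(self.replicates)]


def replicate_seed(seed: int, replicate: int) -> np.random.SeedSequence:
    """Counter-based substream seed: replicate r is reproducible in isolation."""
    return np.random.SeedSequence(entropy=int(seed), spawn_key=(int(replicate),))


def rng_for_replicate(seed: int, replicate: int) -> np.random.Generator:
    return np.random.default_rng(replicate_seed(seed, replicate))


def _require_complete(values: np.ndarray) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    if np.isnan(values).any():
        raise ValueError("randomization requires a complete (imputed) matrix")
    return values


# ---------------------------------------------------------------------------
# P and R: permutations
# ---------------------------------------------------------------------------

def permute_all_values(values: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Uniform permutation of all n*m entries."""
    values = _require_complete(values)
    flat = rng.permutation(values.ravel())
    return flat.reshape(values.shape)


def permute_within_rows(values: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Independent uniform permutation of the values within each row."""
    values = _require_complete(values)
    return rng.permuted(values, axis=1)


def randomize_P(matrix: ExpressionMatrix, seed: int) -> ExpressionMatrix:
    """Null model P: permute the values of all entries of the matrix."""
    rng = np.random.default_rng(seed)
    return matrix.with_values(permute_all_values(matrix.values, rng))


def randomize_R(matrix: ExpressionMatrix, seed: int) -> ExpressionMatrix:
    """Null model R: permute the values within each row of the matrix."""
    rng = np.random.default_rng(seed)
    return matrix.with_values(permute_within_rows(matrix.values, rng))


# ---------------------------------------------------------------------------
# A: parametric AR(1) resampling
# ---------------------------------------------------------------------------

def fit_ar1(row: np.ndarray, method: str = "mle") -> ARParams:
    """Yule-Walker AR(1) fit of a single (standardized) row.

    ``method="mle"`` uses denominator-m autocovariances (the classic
    Yule-Walker convention); ``"adjusted"`` uses denominator m-k.  The
    estimate is clamped into (-0.999, 0.999) with a warning if outside,
    and a zero-variance row gets alpha 0 with a floored innovation variance.
    """
    row = np.asarray(row, dtype=float)
    if row.ndim != 1 or row.shape[0] < 3:
        raise ValueError("AR(1) fit needs a 1-D row with m >= 3")
    if row.std() == 0:
        logger.warning("zero-variance row: alpha=0, z_variance floored")
        return ARParams(np.array([0.0]), np.array([Z_VARIANCE_FLOOR]))
    rho, sigma = yule_walker(row, order=1, method=method, demean=True)
    alpha = float(rho[0])
    if abs(alpha) >= ALPHA_CLAMP:
        logger.warning("alpha=%.4f clamped into (-%.3f, %.3f)",
                       alpha, ALPHA_CLAMP, ALPHA_CLAMP)
        alpha = float(np.clip(alpha, -ALPHA_CLAMP, ALPHA_CLAMP))
    z_var = max(float(sigma) ** 2, Z_VARIANCE_FLOOR)
    return ARParams(np.array([alpha]), np.array([z_var]))


def fit_ar1_matrix(values: np.ndarray, method: str = "mle") -> ARParams:
    """Vectorized per-row Yule-Walker AR(1) fit (same conventions as fit_ar1)."""
    X = _require_complete(values)
    n, m = X.shape
    if m < 3:
        raise ValueError("AR(1) fit needs m >= 3")
    Xc = X - X.mean(axis=1, keepdims=True)
    denom0 = float(m)
    denom1 = float(m) if method == "mle" else float(m - 1)
    r0 = (Xc ** 2).sum(axis=1) / denom0
    r1 = (Xc[:, :-1] * Xc[:, 1:]).sum(axis=1) / denom1
    flat = r0 == 0
    if flat.any():
        logger.warning("%d zero-variance row(s): alpha=0, z_variance floored",
                       int(flat.sum()))
    safe_r0 = np.where(flat, 1.0, r0)
    alpha = np.where(flat, 0.0, r1 / safe_r0)
    out_of_range = np.abs(alpha) >= ALPHA_CLAMP
    if out_of_range.any():
        logger.warning("%d alpha estimate(s) clamped into (-%.3f, %.3f)",
                       int(out_of_range.sum()), ALPHA_CLAMP, ALPHA_CLAMP)
        alpha = np.clip(alpha, -ALPHA_CLAMP, ALPHA_CLAMP)
    z_var = np.maximum(r0 - alpha * r1, Z_VARIANCE_FLOOR)
    z_var = np.where(flat, Z_VARIANCE_FLOOR, z_var)
    return ARParams(alpha, z_var)


def generate_ar1(
    params: ARParams, m: int, rng: np.random.Generator, n: int | None = None
) -> np.ndarray:
    """Simulate AR(1) rows: X_0 = Z_0, X_t = alpha X_{t-1} + Z_t, Z ~ N(0, var)."""
    alpha = params.alpha
    z_sd = np.sqrt(params.z_variance)
    if n is None:
        n = alpha.shape[0]
    alpha = np.broadcast_to(alpha, (n,))
    z_sd = np.broadcast_to(z_sd, (n,))
    Z = rng.standard_normal((n, m)) * z_sd[:, None]
    X = np.empty((n, m))
    X[:, 0] = Z[:, 0]
    for t in range(1, m):
        X[:, t] = alpha * X[:, t - 1] + Z[:, t]
    return X


def randomize_A(
    matrix: ExpressionMatrix,
    seed: int,
    fit_method: str = "mle",
    pooled_alpha: bool = False,
    standardize: bool = True,
) -> ExpressionMatrix:
    """Null model A: per-gene AR(1) fit and parametric resampling.

    With ``pooled_alpha`` a single alpha (the mean of the per-gene
    estimates) is shared by all genes.  Generated rows are re-standardized
    by default because the generating model preserves only the innovation
    variance, not the row variance; pass ``standardize=False`` to obtain
    the raw process values (used by the theory validation).
    """
    rng = np.random.default_rng(seed)
    X = _require_complete(matrix.values)
    params = fit_ar1_matrix(X, method=fit_method)
    if pooled_alpha:
        params = ARParams(
            np.full_like(params.alpha, params.alpha.mean()), params.z_variance
        )
    out = generate_ar1(params, X.shape[1], rng)
    if standardize:
        out = RowStandardizer().fit_transform(out)
    return matrix.with_values(out)


# ---------------------------------------------------------------------------
# S: per-cycle prefix/suffix recombination
# ---------------------------------------------------------------------------

def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def cycle_blocks(m: int, cycles: float) -> list[tuple[int, int]]:
    """0-based [start, stop) time blocks, one per (possibly partial) cycle.

    Cycle ``b`` spans sample indices ``(round((b-1)*m/cycles),
    round(b*m/cycles)]`` (1-based); a trailing partial cycle forms its own
    block.  Every block must hold at least 2 samples.
    """
    if cycles <= 0:
        raise ValueError("cycles must be positive")
    n_blocks = int(np.ceil(cycles - 1e-9))
    edges = [0]
    for b in range(1, n_blocks + 1):
        edges.append(min(_round_half_up(b * m / cycles), m))
    edges[-1] = m
    blocks = [(lo, hi) for lo, hi in zip(edges[:-1], edges[1:]) if hi > lo]
    for lo, hi in blocks:
        if hi - lo < 2:
            raise ValueError(
                f"cycle block [{lo}, {hi}) has fewer than 2 samples; "
                "use fewer cycles or more timepoints"
            )
    return blocks


def prefix_mask(m: int, cycles: float) -> np.ndarray:
    """Boolean length-m mask, true on prefix (first-half-of-cycle) samples.

    Each cycle block is split at its midpoint; when the block length is odd
    the prefix gets the extra sample.
    """
    mask = np.zeros(m, dtype=bool)
    for lo, hi in cycle_blocks(m, cycles):
        mid = lo + int(np.ceil((hi - lo) / 2))
        mask[lo:mid] = True
    return mask


def recombine_prefix_suffix(
    values: np.ndarray, cycles: float, rng: np.random.Generator,
    per_cycle_permutations: bool = False,
) -> np.ndarray:
    """Core of method S on a raw array (one donor permutation per replicate).

    With ``per_cycle_permutations`` each cycle draws its own donor
    permutation (off by default; the standard model combines the prefixes of
    row g with the suffixes of a single row h).
    """
    X = _require_complete(values)
    n, m = X.shape
    if n == 1:
        logger.warning("method S on a single gene: the null is vacuous "
                       "(the only permutation is the identity)")
    if per_cycle_permutations:
        out = X.copy()
        for lo, hi in cycle_blocks(m, cycles):
            mid = lo + int(np.ceil((hi - lo) / 2))
            h = rng.permutation(n)
            out[:, mid:hi] = X[h, mid:hi]
        return out
    mask = prefix_mask(m, cycles)
    h = rng.permutation(n)
    return np.where(mask[None, :], X, X[h])


def randomize_S(
    matrix: ExpressionMatrix, cycles: float, seed: int,
    per_cycle_permutations: bool = False,
) -> ExpressionMatrix:
    """Null model S: recombine per-cycle prefixes and suffixes across genes."""
    rng = np.random.default_rng(seed)
    return matrix.with_values(
        recombine_prefix_suffix(matrix.values, cycles, rng,
                                per_cycle_permutations)
    )


# ---------------------------------------------------------------------------
# dispatch
# ---------------------------------------------------------------------------

def randomize_values(
    values: np.ndarray, method: str, rng: np.random.Generator,
    cycles: float | None = None, ar_params: ARParams | None = None,
    standardize_a: bool = True,
) -> np.ndarray:
    """Array-level dispatcher used by the replicate loops.

    For method A, pre-fitted ``ar_params`` avoid refitting per replicate.
    """
    if method == "P":
        return permute_all_values(values, rng)
    if method == "R":
        return permute_within_rows(values, rng)
    if method == "A":
        params = ar_params or fit_ar1_matrix(values)
        out = generate_ar1(params, values.shape[1], rng)
        return RowStandardizer().fit_transform(out) if standardize_a else out
    if method == "S":
        if cycles is None:
            raise ValueError("method S requires the cycle count")
        return recombine_prefix_suffix(values, cycles, rng)
    raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")


def randomize(
    matrix: ExpressionMatrix, method: str, seed: int,
    cycles: float | None = None, **kwargs,
) -> ExpressionMatrix:
    """Matrix-level dispatcher over the four null models."""
    if method == "P":
        return randomize_P(matrix, seed)
    if method == "R":
        return randomize_R(matrix, seed)
    if method == "A":
        return randomize_A(matrix, seed, **kwargs)
    if method == "S":
        if cycles is None:
            raise ValueError("method S requires the cycle count")
        return randomize_S(matrix, cycles, seed, **kwargs)
    raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
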