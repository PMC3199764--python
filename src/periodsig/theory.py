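"""Closed-form null moments of the modified periodicity score.

These expressions serve as independent oracles for the randomization
implementations: each one is validated against brute-force Monte Carlo in
the test suite, so a transcription or derivation error is caught
mechanically.

The *modified* k-th periodicity score of a row ``x`` of length ``m`` is ::

    Fk(x) = (2/m)^2 * [ (x . cos_k)^2 + (x . sin_k)^2 ]

with ``cos_k[t] = cos(2 pi k t / m)``, ``t = 0..m-1``.  It relates to the
raw score ``F`` of :mod:`periodsig.score` by ``Fk = (2 F / m)^2``.  A
perfect unit-amplitude cycle at frequency k scores exactly 1 for every
``m``, which is what makes the null statistics below comparable across
series lengths: under the value-permuting nulls they shrink as ``m`` grows,
while a genuinely periodic signal holds its score.

Moment expressions
------------------
* P and R are exact finite-population permutation moments: the score is a
  quadratic form ``Q = sum_{t,u} gamma_{tu} e_t e_u`` with
  ``gamma_{tu} = cos(2 pi k (t-u)/m)`` in entries drawn without replacement
  from the value pool (the whole matrix for P, one row for R).  Both
  moments depend only on the pool's second and fourth power sums -- they
  are blind to the time axis.  As the pool grows the expectation approaches
  the i.i.d. form ``4 * mean(x^2) / m``.
* A ("exact" mode) uses the Gaussian quadratic-form identities
  ``E[Q] = tr(M K)``, ``Var[Q] = 2 tr(M K M K)`` over the nonstationary
  AR(1) covariance kernel of ``X_0 = Z_0, X_t = alpha X_{t-1} + Z_t``;
  "asymptotic" mode uses the AR(1) spectral density, putting the
  characteristic cosine in the denominator::

      E[Fk] ~ (4 sigma_z^2 / m) / (1 - 2 alpha cos(2 pi k / m) + alpha^2)

  with relative error O(1/m).
* S works on the genes' empirical frequency-k Fourier coefficients
  ``alpha_gk = (2/m) sum_t x_gt exp(-2 pi i k t / m)``: a recombined row's
  coefficient is ``(alpha_g + alpha_h)/2``, so the null score for donor
  pair (g, h) is ``|alpha_g + alpha_h|^2 / 4`` and the moments are taken
  over all n^2 ordered pairs.  This is exact for pure frequency-k signals
  when m is divisible by 2k and has O(1/m) spectral-leakage error
  otherwise; each frequency randomizes separately, and the statistics do
  not shrink as the sampling rate grows.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Any

import numpy as np

from .matrix_io import ExpressionMatrix
from .randomize import (
    ARParams,
    generate_ar1,
    permute_all_values,
    permute_within_rows,
    recombine_prefix_suffix,
)

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class TheoryMoments:
    """Expectation and variance of a null modified-score distribution."""

    expectation: float
    variance: float
    inputs: dict[str, Any] = dataclasses.field(default_factory=dict)
    error_order: str | None = None

    def __post_init__(self) -> None:
        if self.variance < 0:
            raise ValueError("variance must be non-negative")


# ---------------------------------------------------------------------------
# the modified score and the perfect cycle
# ---------------------------------------------------------------------------

def perfect_cycle(k: int, m: int) -> np.ndarray:
    """Unit-amplitude frequency-k cosine template c_k over t = 0..m-1."""
    t = np.arange(m)
    return np.cos(2.0 * np.pi * k * t / m)


def _fourier_pair(m: int, k: float) -> tuple[np.ndarray, np.ndarray]:
    t = np.arange(m)
    w = 2.0 * np.pi * k / m
    return np.cos(w * t), np.sin(w * t)


def modified_score(row: np.ndarray, k: int) -> float:
    """Modified k-th periodicity score of one row (see module docstring)."""
    row = np.asarray(row, dtype=float)
    m = row.shape[0]
    if m < 2:
        raise ValueError("need m >= 2")
    if k >= m / 2:
        logger.warning("k=%d >= m/2=%.1f: frequency is aliased", k, m / 2)
    c, s = _fourier_pair(m, k)
    return float((2.0 / m) ** 2 * ((row @ c) ** 2 + (row @ s) ** 2))


def modified_scores(values: np.ndarray, k: int) -> np.ndarray:
    """Vectorized :func:`modified_score` over the rows of an (n, m) array."""
    values = np.asarray(values, dtype=float)
    m = values.shape[1]
    c, s = _fourier_pair(m, k)
    return (2.0 / m) ** 2 * ((values @ c) ** 2 + (values @ s) ** 2)


def fourier_coefficients(values: np.ndarray, k: int) -> np.ndarray:
    """Empirical complex frequency-k coefficients alpha_gk, one per row."""
    values = np.asarray(values, dtype=float)
    m = values.shape[1]
    t = np.arange(m)
    return (2.0 / m) * (values @ np.exp(-2j * np.pi * k * t / m))


def _check_frequency(k: int, m: int) -> None:
    if k <= 0:
        raise ValueError("k must be a positive integer")
    if k % m == 0 or (2 * k) % m == 0:
        raise ValueError(
            f"frequency k={k} is degenerate for m={m} (k or 2k is a "
            "multiple of m); the sine/cosine pair is not orthonormal there"
        )


# ---------------------------------------------------------------------------
# exact permutation moments (methods P and R)
# ---------------------------------------------------------------------------

def _permutation_moments(
    pool: np.ndarray, m: int, k: int
) -> tuple[float, float]:
    """Exact moments of Fk when m entries are drawn without replacement.

    ``pool`` is the value population (the whole matrix for P, a single row
    for R); its mean must be ~0, which row standardization guarantees.
    Derived from the joint factorial moments of sampling without
    replacement combined with the trigonometric sums of the quadratic-form
    kernel; exact for every finite (N, m), no asymptotic terms.
    """
    _check_frequency(k, m)
    x = np.asarray(pool, dtype=float).ravel()
    N = x.size
    if N < 4:
        raise ValueError("need a value pool of at least 4 entries")
    if m > N:
        raise ValueError("cannot draw more entries than the pool holds")
    P1, P2, P4 = x.sum(), (x ** 2).sum(), (x ** 4).sum()
    if abs(P1) > 1e-8 * max(1.0, np.sqrt(N * P2 / max(N, 1))) * N:
        logger.warning("value pool mean %.3g is not ~0; permutation moments "
                       "assume standardized rows", P1 / N)
    # distinct-position joint moments of the draw
    M2 = P2 / N
    M4 = P4 / N
    D11 = -P2 / (N * (N - 1))
    D31 = -P4 / (N * (N - 1))
    D22 = (P2 ** 2 - P4) / (N * (N - 1))
    D211 = (2 * P4 - P2 ** 2) / (N * (N - 1) * (N - 2))
    D1111 = (3 * P2 ** 2 - 6 * P4) / (N * (N - 1) * (N - 2) * (N - 3))
    # kernel sums for gamma_{tu} = cos(2 pi k (t-u)/m), k, 2k != 0 mod m
    S1 = m ** 2 / 2 - m          # sum_{t != u} gamma^2
    S2 = m * (2 - m / 2)         # sum over paths t-u, t-w (u, w != t distinct)
    S3 = 2 * m ** 2 - 6 * m      # sum over two disjoint off-diagonal pairs
    EQ = m * M2 + (-m) * D11
    EQ2 = (
        m * M4
        + m * (m - 1) * D22
        + 2 * (-2 * m * D31 + m * (2 - m) * D211)
        + 2 * S1 * D22
        + 4 * S2 * D211
        + S3 * D1111
    )
    var_q = EQ2 - EQ ** 2
    scale = (4.0 / m ** 2)
    return scale * EQ, scale ** 2 * max(var_q, 0.0)


def null_moments_P(matrix: ExpressionMatrix | np.ndarray, k: int) -> TheoryMoments:
    """Null moments of Fk under method P (whole-matrix permutation).

    Depends only on the matrix's value multiset -- the moments of a matrix
    and of any shuffled copy are identical, and they shrink roughly as
    ``4 * mean(x^2) / m`` with growing m.
    """
    values = matrix.values if isinstance(matrix, ExpressionMatrix) else matrix
    values = np.asarray(values, dtype=float)
    n, m = values.shape
    e, v = _permutation_moments(values, m, k)
    mu2 = float((values ** 2).mean())
    mu4 = float((values ** 4).mean())
    return TheoryMoments(e, v, {
        "method": "P", "m": m, "k": k, "N": n * m,
        "mean_sq": mu2, "mean_4th": mu4,
    })


def null_moments_R(
    matrix: ExpressionMatrix | np.ndarray, k: int,
    gene: int | str | None = None,
) -> TheoryMoments:
    """Null moments of Fk under method R (within-row permutation).

    With ``gene`` fixed, the exact per-row moments; with ``gene=None`` the
    moments of the pooled null over all genes (law of total variance over
    a uniformly chosen row).
    """
    if isinstance(matrix, ExpressionMatrix):
        values = matrix.values
        if isinstance(gene, str):
            gene = matrix.gene_ids.index(gene)
    else:
        values = np.asarray(matrix, dtype=float)
        if isinstance(gene, str):
            raise TypeError("gene by ID requires an ExpressionMatrix")
    n, m = values.shape
    if gene is not None:
        e, v = _permutation_moments(values[gene], m, k)
        return TheoryMoments(e, v, {"method": "R", "m": m, "k": k,
                                    "gene": int(gene)})
    per_row = [_permutation_moments(values[g], m, k) for g in range(n)]
    es = np.array([e for e, _ in per_row])
    vs = np.array([v for _, v in per_row])
    e_pool = float(es.mean())
    v_pool = float(vs.mean() + es.var())
    return TheoryMoments(e_pool, v_pool, {"method": "R", "m": m, "k": k,
                                          "pooled_over": n})


# ---------------------------------------------------------------------------
# method A: AR(1) resampling
# ---------------------------------------------------------------------------

def ar1_covariance_kernel(alpha: float, z_variance: float, m: int) -> np.ndarray:
    """Covariance of (X_0..X_{m-1}) for X_0 = Z_0, X_t = alpha X_{t-1} + Z_t."""
    t = np.arange(m)
    lag = np.abs(t[:, None] - t[None, :])
    lo = np.minimum(t[:, None], t[None, :])
    return z_variance * alpha ** lag * (1 - alpha ** (2 * (lo + 1))) / (1 - alpha ** 2) \
        if alpha != 0 else z_variance * (lag == 0).astype(float)


def null_moments_A(
    alpha: float, z_variance: float, m: int, k: int, mode: str = "exact"
) -> TheoryMoments:
    """Null moments of Fk under method A (AR(1) parametric resampling).

    ``mode="exact"``: Gaussian quadratic-form trace identities over the
    exact (nonstationary) covariance kernel.  ``mode="asymptotic"``: the
    spectral-density form with the cosine in the denominator and stated
    O(1/m) error -- the source of the characteristic bumps when the
    expectation is traced across frequencies.
    """
    if not abs(alpha) < 1:
        raise ValueError("|alpha| must be < 1")
    if z_variance <= 0:
        raise ValueError("z_variance must be positive")
    _check_frequency(k, m)
    w = 2.0 * np.pi * k / m
    spectrum = z_variance / (1.0 - 2.0 * alpha * np.cos(w) + alpha ** 2)
    inputs = {"method": "A", "alpha": alpha, "z_variance": z_variance,
              "m": m, "k": k, "spectral_density": spectrum}
    if mode == "asymptotic":
        return TheoryMoments(4.0 * spectrum / m, 16.0 * spectrum ** 2 / m ** 2,
                             inputs, error_order="O(1/m)")
    if mode != "exact":
        raise ValueError("mode must be 'exact' or 'asymptotic'")
    K = ar1_covariance_kernel(alpha, z_variance, m)
    c, s = _fourier_pair(m, k)
    M = np.outer(c, c) + np.outer(s, s)
    MK = M @ K
    scale = (4.0 / m ** 2)
    e = scale * float(np.trace(MK))
    v = scale ** 2 * 2.0 * float(np.trace(MK @ MK))
    return TheoryMoments(e, v, inputs)


# ---------------------------------------------------------------------------
# method S: prefix/suffix recombination
# ---------------------------------------------------------------------------

def null_moments_S(matrix: ExpressionMatrix | np.ndarray, k: int) -> TheoryMoments:
    """Null moments of Fk under method S, from empirical Fourier coefficients.

    The null score of donor pair (g, h) is ``|alpha_gk + alpha_hk|^2 / 4``;
    expectation and variance are taken over all n^2 ordered pairs (the
    marginal of a uniform donor permutation, fixed points included).
    """
    values = matrix.values if isinstance(matrix, ExpressionMatrix) else matrix
    values = np.asarray(values, dtype=float)
    n, m = values.shape
    _check_frequency(k, m)
    coef = fourier_coefficients(values, k)
    # accumulate pair moments in row chunks to bound memory at O(chunk * n)
    total = 0.0
    total_sq = 0.0
    chunk = max(1, min(n, 2_000_000 // max(n, 1)))
    for lo in range(0, n, chunk):
        pair = np.abs(coef[lo:lo + chunk, None] + coef[None, :]) ** 2 / 4.0
        total += float(pair.sum())
        total_sq += float((pair ** 2).sum())
    e = total / n ** 2
    v = max(total_sq / n ** 2 - e ** 2, 0.0)
    return TheoryMoments(e, v, {"method": "S", "m": m, "k": k, "n": n},
                         error_order="O(1/m) spectral leakage")


# ---------------------------------------------------------------------------
# Monte-Carlo oracle
# ---------------------------------------------------------------------------

def monte_carlo_null_scores(
    values: np.ndarray,
    method: str,
    k: int,
    draws: int,
    seed: int,
    ar_params: ARParams | None = None,
) -> np.ndarray:
    """Brute-force null modified scores: ``draws`` randomizations, all rows.

    Scores are computed on the raw randomized values (no re-standardization)
    to match what the closed forms describe.  For method A, ``ar_params``
    supplies the generating parameters directly.
    """
    values = np.asarray(values, dtype=float)
    rng = np.random.default_rng(seed)
    n, m = values.shape
    out = []
    for _ in range(draws):
        if method == "P":
            rand = permute_all_values(values, rng)
        elif method == "R":
            rand = permute_within_rows(values, rng)
        elif method == "A":
            if ar_params is None:
                raise ValueError("method A needs ar_params for the oracle")
            rand = generate_ar1(ar_params, m, rng, n=n)
        elif method == "S":
            rand = recombine_prefix_suffix(values, float(k), rng)
        else:
            raise ValueError(f"unknown method {method!r}")
        out.append(modified_scores(rand, k))
    return np.concatenate(out)


def fit_moments_report(values: np.ndarray, k: int, draws: int, seed: int):
    """Closed-form vs Monte-Carlo moments for every method, as a DataFrame."""
    import pandas as pd

    from .randomize import fit_ar1_matrix

    values = np.asarray(values, dtype=float)
    params = fit_ar1_matrix(values)
    alpha = float(params.alpha.mean())
    z_var = float(params.z_variance.mean())
    m = values.shape[1]
    closed = {
        "P": null_moments_P(values, k),
        "R": null_moments_R(values, k),
        "A": null_moments_A(alpha, z_var, m, k),
        "S": null_moments_S(values, k),
    }
    rows = []
    for method, moments in closed.items():
        ar = ARParams(np.full(values.shape[0], alpha),
                      np.full(values.shape[0], z_var)) if method == "A" else None
        mc = monte_carlo_null_scores(values, method, k, draws, seed,
                                     ar_params=ar)
        se_mean, se_var = moment_standard_errors(mc)
        rows.append({
            "method": method,
            "expectation_theory": moments.expectation,
            "expectation_mc": float(mc.mean()),
            "se_mean": se_mean,
            "variance_theory": moments.variance,
            "variance_mc": float(mc.var()),
            "se_variance": se_var,
        })
    return pd.DataFrame(rows)


def moment_standard_errors(samples: np.ndarray) -> tuple[float, float]:
    """Monte-Carlo standard errors of the sample mean and sample variance."""
    samples = np.asarray(samples, dtype=float)
    nmc = samples.size
    var = samples.var()
    se_mean = float(np.sqrt(var / nmc))
    central4 = float(((samples - samples.mean()) ** 4).mean())
    se_var = float(np.sqrt(max(central4 - var ** 2, 0.0) / nmc))
    return se_mean, se_var
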