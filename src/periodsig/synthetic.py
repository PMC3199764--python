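"""Synthetic expression matrices with known per-gene ground truth.

The generator emulates the data regimes of short gene-cycle time courses:

* a configurable fraction of *periodic* genes,
  ``amplitude * cos(2 pi cycles t / m + phi_g)`` plus AR(1) noise, with
  phases either synchronized (one shared phase, as in a synchronized
  culture where nearly every expressed gene appears coherently periodic)
  or uniform (desynchronized);
* *background* genes carrying AR(1)-correlated noise -- autocorrelated
  stress-response-like drift is the default background, white noise via
  ``ar1_alpha = 0`` -- optionally plus a shared monotone stress trend
  (exponential decay);
* uniformly random injected missing values.

Every matrix ships with truth labels, enabling realized-FDR and power
evaluation downstream.  Everything is reproducible from the seed.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np

from .matrix_io import ExpressionMatrix

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class GeneratorConfig:
    """Generating parameters for one synthetic matrix.

    amplitude is in the same (arbitrary, log-ratio-like) units as noise_sd;
    the per-gene signal-to-noise ratio is amplitude^2 / (2 * noise_var)
    where noise_var is the stationary AR(1) variance
    noise_sd^2 / (1 - ar1_alpha^2).
    """

    n_genes: int = 100
    m_timepoints: int = 24
    cycles: float = 2.0
    periodic_fraction: float = 0.1
    amplitude: float = 2.0
    phase_mode: str = "uniform"          # "synchronized" | "uniform"
    noise_sd: float = 1.0
    ar1_alpha: float = 0.3
    stress_trend: str = "none"           # "none" | "exponential_decay"
    stress_rate: float = 0.2
    stress_amplitude: float = 1.0
    missing_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.m_timepoints < 2:
            raise ValueError("need n_genes >= 1 and m_timepoints >= 2")
        if self.cycles <= 0:
            raise ValueError("cycles must be positive")
        if not 0.0 <= self.periodic_fraction <= 1.0:
            raise ValueError("periodic_fraction must lie in [0, 1]")
        if self.amplitude <= 0 or self.noise_sd < 0:
            raise ValueError("amplitude must be > 0 and noise_sd >= 0")
        if not abs(self.ar1_alpha) < 1:
            raise ValueError("|ar1_alpha| must be < 1")
        if self.phase_mode not in ("synchronized", "uniform"):
            raise ValueError("phase_mode must be 'synchronized' or 'uniform'")
        if self.stress_trend not in ("none", "exponential_decay"):
            raise ValueError("unknown stress_trend")
        if not 0.0 <= self.missing_fraction < 1.0:
            raise ValueError("missing_fraction must lie in [0, 1)")

    @property
    def n_periodic(self) -> int:
        exact = self.periodic_fraction * self.n_genes
        rounded = int(round(exact))
        if abs(exact - rounded) > 1e-9:
            logger.warning("periodic_fraction * n_genes = %.2f rounded to %d",
                           exact, rounded)
        return rounded

    @property
    def snr(self) -> float:
        """Signal power over stationary noise power for periodic genes."""
        noise_var = self.noise_sd ** 2 / (1 - self.ar1_alpha ** 2)
        return (self.amplitude ** 2 / 2.0) / noise_var if noise_var > 0 else np.inf


def _ar1_noise(config: GeneratorConfig, n: int, rng: np.random.Generator
               ) -> np.ndarray:
    """Stationary AR(1) noise rows with marginal sd noise_sd."""
    m = config.m_timepoints
    if config.noise_sd == 0:
        return np.zeros((n, m))
    a = config.ar1_alpha
    sd = config.noise_sd
    z_sd = sd * np.sqrt(1.0 - a ** 2)
    X = np.empty((n, m))
    X[:, 0] = rng.standard_normal(n) * sd
    for t in range(1, m):
        X[:, t] = a * X[:, t - 1] + rng.standard_normal(n) * z_sd
    return X


def generate(config: GeneratorConfig) -> tuple[ExpressionMatrix, np.ndarray]:
    """Generate a matrix and its per-gene truth labels (True = periodic).

    Periodic genes come first in row order; the truth vector, not the
    ordering, is the contract.
    """
    rng = np.random.default_rng(config.seed)
    n, m = config.n_genes, config.m_timepoints
    n_per = config.n_periodic
    t = np.arange(1, m + 1, dtype=float)
    values = _ar1_noise(config, n, rng)
    if config.stress_trend == "exponential_decay":
        trend = config.stress_amplitude * np.exp(-config.stress_rate * (t - 1))
        values[n_per:] += trend[None, :]
    if n_per:
        if config.phase_mode == "synchronized":
            phases = np.zeros(n_per)
        else:
            phases = rng.uniform(0.0, 2.0 * np.pi, size=n_per)
        signal = config.amplitude * np.cos(
            2.0 * np.pi * config.cycles * t[None, :] / m + phases[:, None]
        )
        values[:n_per] += signal
    if config.missing_fraction > 0:
        mask = rng.random((n, m)) < config.missing_fraction
        # never blank out an entire row or column
        mask[mask.all(axis=1)] = False
        full_cols = mask.all(axis=0)
        mask[:, full_cols] = False
        values = values.copy()
        values[mask] = np.nan
    gene_ids = [f"gene_{i + 1:05d}" for i in range(n)]
    truth = np.zeros(n, dtype=bool)
    truth[:n_per] = True
    matrix = ExpressionMatrix(gene_ids, [f"t{j}" for j in range(1, m + 1)], values)
    return matrix, truth


def figure1_fixture(seed: int = 0) -> ExpressionMatrix:
    """The canonical 10 x 20 demonstration matrix.

    Genes 1-5 are cyclic (two cycles over the series, slight observation
    noise); genes 6-10 are i.i.d. standard normal draws.
    """
    rng = np.random.default_rng(seed)
    m = 20
    t = np.arange(1, m + 1, dtype=float)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=5)
    cyclic = np.cos(2.0 * np.pi * 2.0 * t[None, :] / m + phases[:, None])
    cyclic = cyclic + 0.2 * rng.standard_normal((5, m))
    noise = rng.standard_normal((5, m))
    values = np.vstack([cyclic, noise])
    gene_ids = [f"cyclic_{i}" for i in range(1, 6)] + \
               [f"noise_{i}" for i in range(1, 6)]
    return ExpressionMatrix(gene_ids, [f"t{j}" for j in range(1, m + 1)], values)
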