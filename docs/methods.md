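# Methods

## The statistical problem

A gene-expression time course is an *n* × *m* matrix *E*: *n* genes
measured at *m* consecutive, uniformly spaced timepoints spanning an
assumed *c* cycles of a biological oscillation. *m* is small (9–46 in
typical gene-cycle studies) and control experiments on non-induced cells
are usually absent, so the null distribution of any periodicity statistic
must be estimated from the data itself. The package does this by
randomization: generate surrogate matrices that keep chosen properties of
the data while destroying experiment-wide periodic structure, score them
exactly like the original, and compare.

## Normalization

Missing entries are KNN-imputed (mean of the `knn_k = 10` nearest gene
rows by Euclidean distance over mutually observed columns; scikit-learn's
nan-Euclidean imputer). Each row is then shifted to mean 0 and scaled to
standard deviation 1, using the population (divide-by-*m*) convention
everywhere; constant rows become zero rows with a warning. The identical
pipeline is applied to every randomized matrix before scoring, so original
and null scores are comparable. Re-standardizing P/R/S output is an exact
no-op up to floating point (their rows are permutations or recombinations
of unit-variance rows only in special cases — in general it is a cheap
correction); for A it is essential, because the AR(1) generator preserves
only the innovation variance, not the row variance. Inputs are assumed to
be on a log-ratio-like scale already; no background correction, log
transformation or between-array normalization is attempted.

Timepoint labels are metadata only: all computation uses the sample index
*t* = 1..*m*, i.e. sampling is assumed uniform. Non-uniform designs are
out of scope and should be resampled upstream.

## Periodicity score

`F(x) = |Σ_t x_t e^{iωt}|` at ω = 2πc/m — the magnitude of the projection
onto the sine/cosine pair at the cycle frequency. No normalization
constant is applied: every downstream use (ranks, δ_s thresholds,
empirical p-values, FDR thresholds) compares scores within one fixed
(matrix, *m*) context, so only relative magnitude matters. A pure
standardized cosine reaches m/√2; i.i.d. standardized noise gives
E[F²] = m.

The effective cycle count `c_adj` is found by exhaustive grid search over
{0.01, 0.02, …, 2c}, maximizing Σ_g F(g); ties break toward the smaller
candidate and the full objective curve is retained. On pure noise the
objective is flat; when max/median < 1.05 the result carries a
low-confidence flag (logged, never fatal). With random phases the
detected optimum can sit one 0.01 grid step off the generating value even
without noise (spectral-leakage imbalance across phases), which is the
resolution this procedure claims.

## Null models

* **P** permutes all *n·m* entries: keeps only the global value multiset.
* **R** permutes within each row independently: keeps each gene's value
  multiset.
* **A** fits per-gene AR(1), `X_t = αX_{t−1} + Z_t`, by Yule–Walker
  (`method="mle"`, the classic biased-autocovariance convention, matching
  the lineage of autocorrelation background models for expression data;
  the denominator-(m−k) variant is available) and resamples rows with
  `X_0 = Z_0` and Gaussian innovations. α is clamped into (−0.999, 0.999)
  and the innovation variance floored at 1e−12 for degenerate rows. Note
  the process with |α| < 1 is a stationary-limit autoregression, not a
  martingale; it is implemented exactly as defined. A pooled-α mode
  exists but is off by default.
* **S** partitions the time axis into per-cycle blocks — cycle *b* spans
  1-based samples (round((b−1)m/c), round(bm/c)], a trailing partial
  cycle forming its own block — splits each block at its midpoint (prefix
  gets the extra sample when odd), draws **one** uniform permutation *h*
  of the genes, and gives row *g* its own prefixes plus the suffixes of
  row *h(g)*. Every column's value multiset and the within-prefix /
  within-suffix column correlations survive; global trends (e.g. a shared
  stress response) survive too, while experiment-wide cyclic phase
  coupling is destroyed. By default S splits at the detected `c_adj` when
  detection is run, else at the reported *c*. An independent-per-cycle
  permutation mode exists, off by default. Blocks shorter than 2 samples
  are an error; with a single gene the null is vacuous and a warning is
  logged.

Conservation laws (P: global multiset; R: row multisets; S: column
multisets; A: none) are asserted bit-exactly in the tests.

Each user seed expands to counter-based per-replicate substreams
(`SeedSequence(seed, spawn_key=(r,))`), so replicate *r* is reproducible
in isolation and results are independent of execution order.

## Significance

Empirical one-tailed p-value with add-one smoothing:
`p(g) = (1 + #{r: F(g,r) ≥ F(g)}) / (R+1)`. The +1 keeps p > 0 (required
for BH validity); ties count against significance. `per_gene` mode (the
default) compares gene *g* only against its own R null scores; `pooled`
mode uses all *n·R* null scores with denominator *n·R* + 1 and is natural
when the null makes rows exchangeable (P, S). The mode is recorded in the
result provenance.

FDR control:

* **Benjamini–Hochberg** step-up on the empirical p-values
  (statsmodels' implementation; an independently written textbook step-up
  serves as the test oracle).
* **Futschik–Herzel threshold**: `FH(f) = [#{(g,r): F(g,r) ≥ f}/R] /
  #{g: F(g) ≥ f}`, evaluated at every observed original score. Since FH
  is a step function, exact equality FH(f) = q is generically
  unattainable; the smallest observed score with FH(f) ≤ q is selected
  (+∞ and zero calls when none qualifies). The FH precondition is
  0 < q < 1: at q = 0 the BH route returns zero calls while FH(f) = 0 can
  still hold on separated data, so the two procedures are only compared
  for interior q.

Defaults: R = 1000 replicates for p-value pipelines, R = 100 for
score-distribution experiments, q = 0.05.

## Closed-form null moments (theory module)

Oracles for the randomizers use the *modified* score
`Fk(x) = (2/m)² [(x·cos_k)² + (x·sin_k)²]` (t = 0..m−1), related to the
raw score by `Fk = (2F/m)²`; a unit-amplitude perfect cycle scores exactly
1 at every *m*, so null statistics can be compared across series lengths.
These moments describe the scores of raw randomized values, before
re-standardization (no closed forms are attempted for the
post-standardization scores; Monte Carlo covers that gap).

* **P/R**: the score is a quadratic form in entries drawn without
  replacement from a value pool (whole matrix for P, one row for R).
  Combining the factorial joint moments of sampling without replacement
  with the trigonometric sums of the kernel gives *exact* finite-(N, m)
  expressions depending only on the pool's second and fourth power sums —
  time-blind by construction, and ≈ 4·mean(x²)/m as the pool grows, so
  they shrink as *m* grows. Valid for integer frequencies with k and 2k
  not multiples of m; the tests verify them against full permutation
  enumeration (m = 6) and Monte Carlo.
* **A**: exact mode uses the Gaussian quadratic-form identities
  E[Q] = tr(MK), Var[Q] = 2tr(MKMK) over the nonstationary covariance
  kernel of `X_0 = Z_0`; asymptotic mode uses the AR(1) spectral density
  `E[Fk] ≈ (4σ_z²/m) / (1 − 2α cos(2πk/m) + α²)` with O(1/m) relative
  error. The cosine in the denominator makes E(k) concave near k = 0 and
  convex beyond — the characteristic bends visible when tracing the
  expectation across frequencies.
* **S**: a recombined row's frequency-k Fourier coefficient is
  (α_gk + α_hk)/2, so the null score of donor pair (g,h) is
  |α_gk + α_hk|²/4 and moments are taken over all n² ordered pairs (the
  marginal of a uniform donor permutation, fixed points included). Exact
  for pure frequency-k signals when m is divisible by 2k; O(1/m)
  spectral-leakage error otherwise. Each frequency randomizes separately,
  and the statistics are invariant to raising the sampling rate — unlike
  P/R/A, the S null does not dilute genuine periodicity as *m* grows.

Every transcribed formula is tested against its Monte-Carlo oracle (4 SE
at 20 000 draws), so a derivation error fails the suite mechanically.

## Synthetic data

The generator emulates the regimes seen in real gene-cycle data: a
configurable fraction of periodic genes
(`amplitude·cos(2πc·t/m + φ_g)` + AR(1) noise; phases either one shared
value, emulating a synchronized culture, or uniform), AR(1) background
genes (autocorrelated stress-response-like drift is the default,
`ar1_alpha = 0` for white noise), an optional shared exponential-decay
stress trend on background genes, and uniform random missingness (never
blanking a whole row or column). SNR is defined as amplitude²/2 over the
stationary noise variance. Every matrix ships with per-gene truth labels.

What it does *not* emulate: amplitude/phase heterogeneity drawn from real
regulatory programs, gene–gene correlation structure beyond the shared
trend, heteroskedastic or heavy-tailed measurement error, and non-uniform
sampling. Passing tests demonstrate correctness of the machinery and the
claimed mechanisms under these idealized conditions, not performance
guarantees on any particular real dataset.

## Problem sizes used in validation

The suite validates at desk scale, chosen so each statistical check has
clear power: conservation on 100 random matrices; oracle equivalence on
500 random instances (n ≤ 20, R ≤ 5); moment checks at 20 000 Monte-Carlo
draws for m ∈ {8, 24}; p-value-vs-m behavior at m ∈ {12, 24, 48, 96}
with 200 genes × 200 randomizations; threshold fractions on a 1000 × 46
synchronized matrix with 50 randomizations (4000 × 46 with 100 in the
acceptance script); FDR control on 50 mixture seeds (500 genes, 10 %
periodic, R = 299) and BH-vs-FH agreement on 20 seeds (1000 genes,
R = 499). The whole suite runs in well under a minute on one core.

## Known limitations

* Uniform sampling is assumed; no Lomb–Scargle-style treatment of
  irregular designs, no multi-frequency spectra, no phase estimation.
* The closed-form S moments rest on the half-split approximation and are
  only exact for pure in-frequency signals with even per-cycle blocks.
* FWER control (Holm–Bonferroni) and resampling-aware FDR refinements are
  deliberately not implemented; BH on empirical p-values and the FH
  threshold are the two supported procedures.
* Benchmark gene lists are matched by exact identifier; no aliasing.
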