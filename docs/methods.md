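# Methods

## Problem

Public mortality and disease-surveillance systems suppress small counts for
confidentiality: a county-by-age table of event counts y_ik (population
n_ik) is released with every cell below a threshold (typically 10) replaced
by a "suppressed" token. The data are therefore left-censored — for a
suppressed cell only the interval containing the count is known — and in
sparse strata (young age groups, rural counties) a large share of cells can
be censored. `smallcounts` estimates the age-specific rates λ_ik and the
directly age-standardized rates Σ_k π_k λ_ik from such tables, with honest
uncertainty, by treating the suppressed counts as latent variables inside
Bayesian models.

Three estimation routes are implemented, deliberately spanning the range
from naive to fully structured.

## Substitution baseline

Each suppressed count is replaced by the expected count under the
state-wide average rate for that age group,

    y*_ik = λ̄(s_i, k) · n_ik,    λ̄(s, k) = Σ_{j: s_j = s} y_jk / Σ_j n_jk.

State rates are assumed publicly available (state totals rarely fall below
the threshold); when they are not, callers can pass any alternative
`StateRateTable` (e.g. national rates). Substituted values are kept as real
numbers — the rule as stated involves no rounding — and are *not* capped at
threshold − 1, so y* may exceed the censoring bound when the population is
large. By construction every suppressed cell in a state receives the same
rate, and the route yields point estimates with no uncertainty measure;
both properties are the baseline's known weaknesses and part of why the
Bayesian routes exist.

## Poisson-gamma model

For every cell, y_ik | λ_ik ~ Poisson(n_ik λ_ik) with a conjugate prior
λ_ik ~ Gamma(y0_sk + 1/3, n0_sk). The prior parameters read as a prior
number of events (y0, shape) and a prior population (n0, rate), which makes
the prior's informativeness directly comparable to the data: with offset 0
and n = n0, the posterior mean is exactly the average of the prior rate
y0/n0 and the crude rate y/n.

Calibration is empirical-Bayes. Given state rates λ̄(s,k) and a reference
age distribution p_k, we solve per state for the scale c with n0_sk = c·p_k
and y0_sk = λ̄(s,k)·n0_sk such that Σ_k y0_sk equals a fixed total (default
6 prior events per state): c = total / Σ_k λ̄(s,k) p_k. The prior thus
smooths each county toward its state's age profile while staying weakly
informative. The reference age distribution defaults to the
standard-population weights supplied by the user, since a national age
pyramid is data this package does not ship. The small shape offset of 1/3
keeps the posterior well behaved in strata dominated by zero counts, where
a pure Gamma(y0, n0) prior with tiny y0 would put excessive mass near zero.

Under censoring the model is fitted by Gibbs sampling with data
augmentation: alternate (a) λ_ik ~ Gamma(y_ik + y0 + 1/3, n_ik + n0) for
every cell, using the current imputed count in suppressed cells, and
(b) y_ik ~ Poisson(n_ik λ_ik) truncated to the censoring set for suppressed
cells. Without suppression step (b) vanishes and the draws are i.i.d. from
the closed-form posterior — this is the conjugacy oracle the tests check
against.

A known behaviour, reproduced on synthetic data: for cells with rates near
zero, imputation over {0..9} pulls posterior means above the complete-data
crude rates — small-count overestimation is expected from this prior
family, and is visible in the low reliability fractions for the youngest
age group.

## Multivariate CAR spatial model

The structured model is a Poisson log-linear model

    log λ_ik = β_0k + x_ik'β_k + z_ik + φ_ik,

by default intercept-only (x_ik'β_k ≡ β_0k; covariate support is
implemented but off). φ_ik ~ N(0, σ²_k) is an exchangeable effect; z_ik is
a spatial effect that is shrunk toward the values of neighboring areas.
The K per-age spatial fields are coupled by a proper multivariate CAR
prior: vec(z) is zero-mean Gaussian with precision Λ ⊗ M(α), where
M(α) = D_w − αW, W the 0/1 adjacency, D_w the diagonal of neighbor counts,
α ∈ [0,1) a single propriety/autocorrelation parameter shared across ages,
and Λ the K×K between-age precision. Conditionally, each area's K-vector
z_i has mean (α/m_i)·Σ_{j~i} z_j and precision m_i Λ: shrinkage grows with
the number of neighbors, and Λ lets high-count age groups lend strength to
sparse ones. A shared α is the simplest multivariate extension consistent
with modelling between-group correlation; per-age α's were considered out
of scope.

Hyperpriors (all proper, all configurable via `MCARHyper`): β_0k ~
N(0, 100²); Λ ~ Wishart(K+1, I_K); σ²_k ~ InverseGamma(0.5, 0.0005) (the
convolution-model convention for exchangeable-effect variances); α ~
Uniform(0,1). These are this package's own weakly-informative choices.
Isolated areas (no neighbors) drop out of M(α); their z_ik gets an
independent N(0, 100) prior instead.

### Sampler

One sweep updates, in order:

1. β_0k: scalar random-walk Metropolis per age.
2. z: single-site random-walk Metropolis, vectorized over graph-color
   blocks at fixed age. Cells of one color at one age are conditionally
   independent given everything else (same-color areas are non-adjacent, so
   M couples them to other colors only; cross-age coupling through Λ is to
   fixed coordinates), so the block's accept/reject decisions are exact
   single-site moves. The prior increment uses the decomposition
   ΔQ_i = ½Λ_kk m_i (z'² − z²) + (z' − z)(−αΛ_kk Σ_{j~i} z_jk + (Mc)_i)
   with c_j = Σ_{k'≠k} Λ_kk' z_jk'.
3. Re-centering: z_·k loses its mean, which is absorbed into β_0k —
   breaking the intercept/field flat direction without changing λ.
4. φ: cell-wise Metropolis (all cells independent given the rest).
5. Λ | z: conjugate Wishart(ν0 + I*, (V0⁻¹ + Z'M(α)Z)⁻¹), I* the number of
   non-isolated areas.
6. σ²_k | φ: conjugate inverse-gamma.
7. α: Metropolis on the logit scale. The determinant term uses
   log|M(α)| = Σ log m_i + Σ log(1 − αω_i), with ω the eigenvalues of
   D^{-1/2} W D^{-1/2} computed once up front, so each proposal costs O(I).
8. Suppressed counts: exact truncated-Poisson draws at the current rates
   (enumeration over the ≤10-point censoring set, normalized in log space —
   deterministic cost and exact distribution, no rejection loops). This is
   the last step of the sweep so the stored (λ, imputed-count) pair is
   coherent.

Step sizes adapt by Robbins–Monro toward 44% acceptance during burn-in only
and are frozen afterwards, preserving detailed balance for the retained
draws. Defaults: 2 chains, 5,000 burn-in, 10,000 retained draws per chain,
thinning 1. A Gelman–Rubin R̂ > 1.05 on a random 50-cell subset logs a
warning, never an error. All randomness flows from one integer seed through
`numpy.random.SeedSequence` spawning, so runs are bit-reproducible.

## Censoring conventions

The censoring set is {0,…,t−1} by default (counts *below* the threshold are
suppressed, zeros included). Data dialects that display exact zeros are
supported with `zero_visible=True`, which changes the set to {1,…,t−1};
the suppression operator, both samplers' imputation kernels, and the DIC
all honor the configured set. Grid completeness is enforced at read time —
a missing (area, age) row is an error, never an implicit zero, because
silent zero-filling would bias rates downward.

## Posterior summaries

Standardized rates are computed draw-wise, λ_i·^(l) = Σ_k π_k λ_ik^(l), so
censoring and estimation uncertainty propagate into the standardized
estimate exactly; summarizing first and standardizing after gives a
different (wrong) answer for skewed posteriors, and a test asserts the
difference. Point estimates are posterior medians; intervals are the
2.5/97.5 empirical percentiles with linear interpolation between order
statistics (numpy's "linear" rule, fixed for reproducibility). A rate is
flagged *reliable* when its posterior relative standard error (SD/median)
is below 0.25 — a pragmatic surveillance-style precision cut-off chosen
here, adjustable per call.

## Model comparison

DIC = D̄ + p_D with p_D = D̄ − D(θ̄). Under censoring the default deviance
is the **observed-data** likelihood: an unsuppressed cell contributes
−2·log Pois(y; nλ), a suppressed cell −2·log Σ_{j∈C} Pois(j; nλ). This
keeps DIC comparable across models regardless of how each imputes; the
augmented complete-data deviance is available via `method="complete"`. The
plug-in point θ̄ is the posterior mean of λ (not of log λ); both choices
are documented and the former is the default. p_D can be negative for
pathological posteriors; it is logged, not raised. Correlation comparisons
replicate the standard design: age-specific correlations with the
complete-data rates over suppressed cells only, standardized-rate
correlations over all areas.

## Synthetic studies

The generator emulates the structure such models face in practice:
log-normal populations (default median ≈ 3,000 per cell, log-SD 1.2, so the
population distribution is heavily right-skewed), age-specific baseline
rates rising steeply with age (defaults 1, 10, 50 events per 10,000, giving
a preponderance of zero and near-zero counts in the youngest group),
spatial fields drawn exactly from the MCAR prior (α = 0.95, between-age
correlation 0.6, log-scale SD 0.4) by Cholesky factorization of M(α) and of
the between-age covariance, and a small exchangeable effect (SD 0.1).
Areas sit on a rook-adjacency lattice — the grid analogue of counties
sharing a border — partitioned into contiguous column-block states so state
pooling is exercised. The default 20×20, K = 3 study yields roughly a third
of cells suppressed at threshold 10; a problem size of 400 areas and three
age groups keeps a full two-model comparison at full chain length
comfortable on a single CPU while exercising every code path. K = 6 and
larger lattices are plain configuration changes.

What passing on these data does and does not show: the generator matches
the MCAR model's own hierarchy, so parameter-recovery and coverage results
demonstrate the correctness of the samplers and the internal consistency of
the machinery — not robustness to real-data features such as irregular
adjacency structure, population pyramids varying across counties,
non-Gaussian spatial heterogeneity, or model misspecification generally.
The qualitative comparison findings (spatial shrinkage spends far fewer
effective parameters; substitution flattens within-state heterogeneity)
are structural and carry over.

## Numerical notes and limitations

- Truncated-Poisson sampling by exact enumeration is preferred to rejection
  for its deterministic cost; log-space normalization keeps it stable up to
  means of at least 1e6.
- The eigendecomposition backing the α update is dense and performed once;
  for very large I (tens of thousands of areas) a sparse determinant method
  would be needed.
- Posterior draws are stored densely (L × I × K); at the default chain
  lengths and study size this is ~200 MB per model. Thinning is the lever
  for larger grids.
- The Poisson-gamma route requires state rates from somewhere — complete
  data in simulation studies, public state totals in real use. If a state's
  own totals are suppressed, supply an alternative `StateRateTable`.
- No covariate-confounding diagnostics; covariate support is minimal and
  off by default.
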