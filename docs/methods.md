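# Methods

This note records the statistical model, the numerical choices behind the
implementation, what the synthetic-data generator does and does not emulate,
and the design decisions taken where several reasonable options existed.

## Indirect standardization

National stratum rates are pooled from the analysed table itself by default,
`r_s = Σ_i O[i,s] / Σ_i n[i,s]`, over the 16 strata {male, female} × 8 age
bands (under 20, 21–30, …, over 80).  This forces the conservation identity
`Σ_i E_i = Σ_i O_i`, so the population-weighted national SMR is exactly 1.
Externally published rates can be supplied instead, in which case
conservation no longer holds.  Stratum labels are opaque strings: the age
bands are never parsed numerically, and any stratification can be used by
passing a schema (the 16-fold cross is enforced by default because the
standardization loses meaning when sexes or broad age groups are pooled).

Areas with `E_i = 0` cannot enter the log-offset model; they are excluded
from fitting with a recorded warning rather than an error, because empty
areas occur in real registries.  An `E_i = 0` area with `O_i > 0` is an
inconsistency and raises.

## The Leroux CAR model

Likelihood and prior are as in the README.  Choices that the model statement
leaves open:

* **Priors** (configurable; weakly informative defaults standard in CAR
  disease mapping): `β_j ~ N(0, 1e5)` per coefficient, `τ² ~ InvGamma(1,
  0.01)`, `ρ ~ U[0, 1)`.  Negative spatial dependence (ρ < 0) is excluded
  by construction; the Leroux parameterisation targets positive
  autocorrelation, which is also the empirically relevant regime for
  mortality surfaces.
* **Identifiability.** The intercept and the mean of the spatial field are
  confounded; after every sweep φ is recentred to mean zero and the mean is
  absorbed into the intercept.  Consequently the estimable intercept is
  `β₀ + mean(φ_true)`, which is what recovery tests compare against.
* **Covariate scaling.** Covariates are centered and scaled internally for
  sampling; coefficients are transformed back, so reported summaries (and
  RRs) refer to the data's original units.
* **sSMR definition.** The smoothed SMR is the per-area posterior *median*
  of `exp(β₀ + φ_i)` from the intercept-only model, matching the
  median-based reporting of the coefficient table.
* **Single chain** by default, summarised by posterior medians and
  equal-tailed 95% credible intervals with one Geweke z per parameter; a
  user wanting multiple chains can run the fit under different seeds.
* **Isolated areas** (islands) stay in the model; their prior reduces to
  `N(0, τ²/(1−ρ))`, which is proper for all ρ in [0, 1).

## Sampler

Metropolis-within-Gibbs:

* `β`: blockwise Gaussian random walk preconditioned with the inverse
  square-root curvature of the Poisson log-likelihood at the initial state,
  adapted toward 23% acceptance.
* `φ_i`: single-site random walks adapted toward 40% acceptance.  The sweep
  is executed color class by color class under a greedy graph coloring;
  within a class no two areas are adjacent, so the vectorised simultaneous
  update is exactly the sequential single-site sweep.  The site-wise prior
  contribution uses the Leroux full conditional: mean
  `ρ Σ_j w_ij φ_j / (ρ w_i+ + 1−ρ)`, variance `τ²/(ρ w_i+ + 1−ρ)`.
* `τ²`: conjugate inverse-gamma Gibbs draw with shape `a + n/2` and rate
  `b + φ'Qφ/2`.
* `ρ`: random walk on the logit scale with the Jacobian correction;
  `log det Q(ρ) = Σ_k log(ρ λ_k + 1 − ρ)` over the precomputed eigenvalues
  of `diag(w₊) − W`, making every evaluation O(n) after one dense
  eigendecomposition per graph.

Adaptation uses a Robbins–Monro update with gain decaying as `t^-0.6`,
active only during burn-in and frozen afterwards so the retained chain is
Markovian.  Divergence (non-finite state) raises with the iteration index.
Identical configuration + seed produces bit-identical sample paths.

Defaults are 110,000 iterations with 10,000 burn-in and no thinning.  The
test suite runs scaled-down chains (2,500–50,000 iterations on lattices of
36–400 areas) chosen so each property being tested — shrinkage direction,
coverage, reductions — is already stable at that size; the recovery study
uses 50 replicates of a 20×20 lattice at 20,000 iterations.

## Diagnostics

**Moran's I** uses row-standardised binary contiguity weights by default
(the common convention in disease mapping; plain binary is selectable, and
the style is always recorded in the output because the choice changes the
statistic).  Inference is by random relabeling (default 999 permutations)
with the add-one p-value rule, two-sided by default with one-sided options;
the analytic null expectation `−1/(n−1)` is reported alongside.  Permutation
rather than normal-approximation inference is the default because SMR-like
surfaces are right-skewed.

**VIF.** `VIF_j = 1/(1−R²_j)` from an OLS regression of covariate j on the
others plus an intercept.  Exact linear dependence is reported as an
infinite VIF (not an exception); constant columns are errors.  The screen
removes the single worst covariate above the threshold (default 2.5),
recomputes, and repeats; ties break toward the earlier column.  Screening
that would leave fewer than two covariates is treated as degenerate and
raises.  By default the pipeline screens only the socioeconomic covariates:
the health-workforce exposures are the quantities of interest and should
not be auto-dropped; the screened set is user-configurable.

**Geweke.** `z = (x̄_A − x̄_B)/√(ŝ_A/n_A + ŝ_B/n_B)` comparing the first
10% window against the last 50%, with the zero-frequency spectral density
estimated by a Bartlett-windowed autocovariance sum truncated at
`L = round(n^{1/3})` lags.  The cube-root truncation keeps the estimator's
own sampling noise small enough that on independent chains the
`|z| ≥ 1.96` flag fires at close to its nominal 5% rate (the calibration
test requires 3–7% over 1,000 replicates), while still absorbing the
autocorrelation actually present in MCMC output.

## Synthetic-data generator

The generator emulates the statistical structure of a national
municipality-level mortality dataset: ~1,900 areas on an irregular
planar-ish contiguity graph (Delaunay triangulation of random points, mean
degree ≈ 6) or a rook/queen lattice; stratum populations log-uniform over
three orders of magnitude (default 10^1.5–10^4.5 per stratum cell);
national stratum rates scaled like Japanese suicide rates around 2010
(~2.4 per 10,000 overall, male ≈ 2.5× female, rising into midlife);
covariates with Gaussian (or log-normal) marginals in published descriptive
ranges, one engineered pair (income vs university-graduate share) at
correlation 0.829, and a psychiatrist-presence Bernoulli indicator at 0.55;
spatial effects drawn exactly from the Leroux prior (ρ = 0.8, τ² = 0.1 by
default); counts Poisson with the expected-count offset, allocated to
strata by a multinomial on expected shares (capped by stratum population).

Two generator choices depart from taking published regression coefficients
at face value, both because the published coefficient scales cannot be
reconciled with the published covariate scales:

* The default true intercept is chosen so the mean linear predictor is
  zero (national mean risk ≈ 1), consistent with internally standardized
  offsets; an explicit intercept can be set.
* The default population-density effect is −0.0002 per density unit rather
  than the order of 10⁻³ a national fit reports, because combined with the
  generator's density marginal (median ≈ 600, long right tail) a larger
  magnitude would drive risks to e^{−20}; the chosen value yields realistic
  risk variation.  The university-graduate share has no direct effect — it
  is the screened-out variable — and acts only through its correlation with
  income.

`expectation_mode` replaces the count draws with rounded expectations while
keeping all structural randomness (covariates, populations, field) a
deterministic function of the config seed, enabling exact-value downstream
tests.  A truth record (β, ρ, τ², φ, risks, offsets, bookkeeping totals)
accompanies every dataset so each intermediate quantity can be recomputed
independently.

What the generator does **not** emulate: real geography and
municipal-boundary contiguity, covariate marginals beyond
order-of-magnitude realism, spatial structure in the covariates themselves,
amalgamation/boundary-change bookkeeping, and any non-Poisson dispersion.
Passing tests therefore demonstrate correctness of the machinery under the
stated generative model, not agreement with any particular national
dataset — the published data-dependent headline numbers (mean sSMR, its
Moran's I, the exact six-covariate VIFs) are functions of an unreleased
dataset and are not reproduction targets.

## Numerical notes and edge cases

* Leroux precision is assembled sparse; log-determinants come from the
  one-time eigendecomposition (exact match with dense `slogdet` to 1e-8 is
  part of the test suite).
* Quantiles are empirical with linear interpolation (equivalent to a full
  sort; checked against a sort-based oracle).
* GAL files are symmetrized by union when asymmetric, with a warning
  recorded (published neighbor lists are frequently one-directional);
  adjacency is re-indexed to the area-table order.
* Moran's I on a constant vector, an edgeless graph, or with fewer than 99
  permutations is an error, as is a Geweke window with zero variance or a
  chain shorter than 100.
* `R² ≥ 1 − 1e-12` in a VIF regression is reported as infinite.

## Known limitations

* Single-CPU dense eigendecomposition limits graphs to a few thousand
  areas; that covers national municipality systems but not fine grids.
* The sampler is a random-walk scheme; strongly informative data with many
  covariates would mix faster under gradient-based methods.
* No model comparison (DIC/WAIC), no BYM/intrinsic alternatives beyond the
  ρ-limits, no spatially varying coefficients, and no mapping/choropleth
  output.
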