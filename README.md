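# caremap

Small-area disease mapping in Python: indirect age-sex standardization,
spatially smoothed standardized mortality ratios (sSMR), and
covariate-adjusted relative risks from a hierarchical Bayesian Poisson model
with Leroux conditional-autoregressive (CAR) spatial random effects —
plus the supporting diagnostics (Moran's I, VIF screening, Geweke
convergence checks).

It is written for epidemiologists and health-services researchers who study
geographic variation in mortality or event rates across many small
administrative areas (for example ~1,900 municipalities), where raw
standardized ratios are dominated by Poisson noise in sparsely populated
areas and spatial smoothing is required before any covariate effect can be
interpreted.

## The model

For areas $i = 1, \dots, n$ with observed counts $O_i$, populations
$n_{is}$ in sex–age strata $s$, and area-level covariates $x_i$:

**Indirect standardization.** National stratum rates
$r_s = \sum_i O_{is} / \sum_i n_{is}$ give expected counts
$E_i = \sum_s r_s\, n_{is}$ and the raw ratio $\mathrm{SMR}_i = O_i / E_i$.
Standardization conserves totals: $\sum_i E_i = \sum_i O_i$.

**Spatial Poisson model.** With the expected count as offset,

$$O_i \mid \eta_i \sim \mathrm{Poisson}\!\big(E_i e^{\eta_i}\big), \qquad
\eta_i = x_i^\top \beta + \phi_i,$$

$$\phi \sim \mathrm{MVN}\!\big(0,\ \tau^2 Q(\rho, W)^{-1}\big), \qquad
Q(\rho, W) = \rho\,(\mathrm{diag}(w_+) - W) + (1-\rho)\,I,$$

where $W$ is the binary contiguity matrix (areas as nodes, shared borders
as edges) and $w_+$ its row sums.  The Leroux precision $Q$ interpolates
between independent random effects ($\rho = 0$) and the intrinsic CAR
($\rho \to 1$) and is proper for every $\rho \in [0, 1)$.  The model is fit
by Metropolis-within-Gibbs MCMC (default 110,000 iterations, 10,000
burn-in); the smoothed SMR is the posterior median of
$e^{\beta_0 + \phi_i}$ from the intercept-only model, and covariate
relative risks are $\mathrm{RR}_j = e^{\beta_j}$ with credible bounds
exponentiated from the coefficient quantiles.

Diagnostics: global Moran's I with permutation inference for spatial
autocorrelation, variance inflation factors with an iterative greatest-VIF
drop rule (threshold 2.5) for collinearity, and Geweke z-scores
(spectral-variance based, $|z| < 1.96$) for MCMC convergence.

## Worked example

Fitting the covariate model on a simulated 15×15-lattice dataset whose true
log-relative-risks are known (`python examples/05_leroux_fit_rr.py`):

```
           median   q2.5  q97.5  geweke_z     rr  rr_lower  rr_upper
parameter
intercept   0.217  0.185  0.249    -0.283    NaN       NaN       NaN
z1          0.274  0.231  0.317    -1.125  1.315     1.260     1.373
z2         -0.186 -0.228 -0.144     2.130  0.830     0.796     0.866
tau2        0.104  0.071  0.148     2.170    NaN       NaN       NaN
rho         0.713  0.396  0.941     0.468    NaN       NaN       NaN

true slopes: z1 = 0.3, z2 = -0.2  (true rho = 0.8, tau2 = 0.1)
```

The 95% credible intervals for both slopes cover the truth; `rr` is the
multiplicative effect of one covariate unit on the event rate (a unit of
`z1` raises the rate by ~32%).  The other examples each demonstrate one
capability — standardization, smoothing/shrinkage, Moran's I, the VIF
screen, and the end-to-end pipeline:

```sh
python examples/01_standardize_smr.py
...
python examples/06_full_pipeline.py
```

The same steps are available from the shell: `caremap simulate`, `caremap
smr`, `caremap moran`, `caremap vif`, `caremap fit`, `caremap ssmr`, and
`caremap pipeline --config run.json`, which runs the whole sequence
(SMR → sSMR → Moran's I → VIF screen → CAR fit) and writes a
reproducibility manifest alongside the artifacts.

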