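# Methods

## The demographic model

`mrrkit.popan` implements the Schwarz–Arnason (superpopulation)
parameterization of the Jolly–Seber open-population model. Per sex group
of size `N`: entry probabilities `pent_1..K` over the `K` sampling
occasions (summing to 1), survival `phi_1..K-1` between consecutive
occasions, detection `p_1..K`. The probability of an observed encounter
history with first detection `f` and last detection `l` is

    P(w) = psi_f * p_f * prod_{j=f+1..l} phi_{j-1} p_j^{w_j} (1-p_j)^{1-w_j} * chi_l

with `psi` the present-but-not-yet-detected recursion
(`psi_1 = pent_1`, `psi_{j+1} = psi_j (1-p_j) phi_j + pent_{j+1}`) and
`chi` the never-seen-again recursion. The full likelihood multiplies the
observed-history terms by the binomial component for the `N - n` members
never detected, whose probability is `sum_b pent_b xi_b` with
`xi_j = (1-p_j)((1-phi_j) + phi_j xi_{j+1})`. The implementation is
validated against a brute-force oracle that enumerates every
(entry, death) pair for all `2^K` histories at `K <= 5` and checks both
per-history equality and normalization to 1.

Assumptions are the usual Jolly–Seber set: homogeneous rates within a
group and occasion, no mark loss, instantaneous sampling, and entries
that are new individuals (no temporary emigration).

### Links and design matrices

- `phi`, `p`: logit link; `N`: log link; `pent`: multinomial logit
  (softmax) applied within each group, reference cell at the first
  occasion.
- Time covariates: `T` is the occasion index centered and scaled to unit
  SD; `T^2` denotes a quadratic *trend*, i.e. columns `T` and `T^2`
  together. A pure-quadratic column without the linear term would not be
  invariant to the centering, so the trend form is the only sensible
  reading.
- `+` shares time coefficients across groups with a group offset; `*`
  adds group-specific time coefficients.
- Because the softmax is invariant to within-group constants, intercept
  and group-offset columns are dropped from `pent` designs:
  `pent(g+T)` fits the same model as `pent(T)`, and `pent(g)` the same
  as `pent(.)` (uniform entry). The same confounding exists in MARK's
  mlogit parameterization.
- Occasion-level covariates (sampling effort on `p`) are standardized
  like `T`. Effort combined with factorial time is exactly collinear
  with the occasion dummies; the rank check rejects such designs naming
  the confounded columns rather than silently dropping one.

### Optimization and uncertainty

Maximum likelihood by L-BFGS-B with box bounds (+-15 on logit/softmax
coefficients, keeping rates within ~3e-7 of 0/1 and the arithmetic
finite; wide log-scale bounds on `N`). Starts: one warm start (detection
frequency heuristic, `N = 2n`) plus up to five random perturbations,
stopping early once two starts agree on the optimum within 1e-4.
`N < n` is handled with a smooth quadratic barrier rather than a hard
wall so line searches retain gradient information. Convergence is
declared at optimizer success plus a gradient norm below
`1e-3 * max(1, |NLL|)` — an absolute threshold is unattainable with
finite-difference gradients on likelihoods of order 1e3. Standard errors
come from the inverse observed information (numerical Hessian); `N` and
the daily-abundance path use delta-method SEs via a numerical Jacobian.
Daily abundance follows `B_t = N pent_t`, `N_1 = B_1`,
`N_{t+1} = N_t phi_t + B_{t+1}`, so entrants conserve the
superpopulation.

### Model selection and dispersion

`QAICc = -2lnL/c-hat + 2K_p + 2K_p(K_p+1)/(n_eff - K_p - 1)` with
`n_eff` = number of marked individuals (configurable). `c-hat` can be
supplied manually, taken as deviance/df, or estimated by parametric
bootstrap: simulate from the fitted general model, refit, and divide the
observed deviance by the mean simulated deviance. "Deviance" here is
twice the gap to the saturated conditional multinomial over observed
histories, computed identically for observed and simulated data, so the
null calibration (`c-hat ~ 1` when the model is true) holds by
construction. Values below 1 (underdispersion) are used as-is by
default; a `clamp_chat` flag enforces the common `max(c-hat, 1)`
convention. Model averaging renormalizes Akaike weights over the kept
subset and reports Buckland unconditional SEs
`sum_i w_i sqrt(var_i + (theta_i - theta_bar)^2)`.

The candidate model set is user-declared (a list of formula strings);
nothing is auto-enumerated. Parameter counts are design-matrix column
counts, which can differ from other software that counts confounded or
boundary parameters differently.

## Dispersal

Coordinates are projected with a spherical azimuthal-equidistant
projection centered on the point-cloud centroid; at a <= 10 km site the
planar error is far below 0.1% (checked against the geodesic closed form:
0.001 deg latitude ~= 111.2 m). The per-individual statistic entering the
distance-class table is the first-recapture displacement (a
`max_displacement_m` alternative is available); lifespan movement is the
sum of consecutive-capture segments. Inverse cumulative class proportions
use class midpoints `w/2, 3w/2, ...` as representative distances — the
midpoint convention keeps `ln D` defined in the first class for the
power-law fit. Kernels are fitted by OLS on the log scale (`ln I` on `D`
for the exponential, on `ln D` for the power law), zero-proportion
classes excluded, with at least three usable classes required. Best
kernel/interval is chosen by R² with ties broken toward the larger
width (fewer, better-populated classes), recorded in the output.
Extrapolations report `100 * I(D)`; `I` is fitted and stored as a
proportion throughout.

## Behaviour statistics

Chi-squared homogeneity is Pearson's statistic without continuity
correction (optional Yates flag for 2x2), with a warning when expected
counts drop below 5. First-record deduplication keeps each individual's
earliest record. Wing series use day indices counted from the series'
first sampling day; days with fewer than five specimens carry no
regression weight. Slope differences are F-tests on the time-by-group
interaction in the pooled `mean ~ day * group` model fitted to the daily
means. Mann–Whitney U switches from the exact distribution to the
tie-corrected normal approximation when either sample exceeds n = 20 or
ties are present. The protandry index — the female-minus-male offset of
the 50% cumulative-recruitment day, linearly interpolated from the
fitted entrants `B_t` — is this package's own quantification of a
pattern usually judged from abundance curves; positive values mean males
recruit earlier.

## Synthetic data

The generator draws, per individual: entry occasion from `pent`, daily
Bernoulli survival, Bernoulli detection (scaled by a per-occasion effort
multiplier normalized to mean 1), an isotropic random-walk step each day
alive (exponential or Pareto step lengths), a wing score
`clip(1 + round(wear_rate * age + noise), 1, 4)` with one Gaussian noise
draw per individual, and multinomial behaviour / nectar-genus labels per
capture. Only detected events are emitted; the generating truth is
returned separately (sealed to a `.truth.json` file by the CLI) so
analysis code cannot read it by accident. One seeded generator is
threaded through all draws in a fixed order, making outputs byte-identical
under a fixed seed.

What the generator does *not* emulate: home-range attraction or site
fidelity, habitat structure and edge effects, weather-dependent
detectability, mark loss, and heterogeneous individual catchability.
Passing recovery tests therefore demonstrate correctness of the
estimators under the models' own assumptions, not robustness to these
real-data violations.

Presets: `gen1-like` (21 occasions, 155 per sex, logistic-peak entry
with the female peak 4 days after the male — protandry; detection 0.45 /
0.35; exponential steps, means 60 / 90 m per day) and `gen2-like`
(28 occasions, 382 males / 276 females, synchronous entry, lower
detection 0.25 / 0.18, slower wing wear, and a heavy-tailed Pareto step
kernel for females). The magnitudes mirror a published two-generation
study; they are pastiches for testing, not data. Daily step means were
set so that first-recapture displacements after the typical 2-day gap
land near the 100/150 m field magnitudes.

## Problem sizes and calibration checks

The test and acceptance runs use sizes that keep the whole suite in the
tens of seconds while leaving Monte-Carlo error well below the asserted
tolerances: 100 replicate studies (K = 20, N = 300 per sex, phi = 0.8,
p = 0.4, beta(3,3)-shaped entry) for recovery — asserting median relative
bias of `N_hat` under 5% and Wald log-scale coverage in [88%, 100%];
B = 100 bootstrap replicates for the null `c-hat`; 2000 null replicates
for the 5%-level type-I error of the chi-squared and U tests (accepted
band [3%, 7%]). The recovery fits use `Phi(.) p(.) pent(T^2) N(g)`: the
quadratic-trend softmax closely matches the discretized beta entry while
keeping each fit a six-parameter problem.

## Known limitations

- No RELEASE-style goodness-of-fit decomposition; dispersion handling is
  bootstrap/deviance/manual only.
- No CJS-only, multistate, or Bayesian variants.
- SEs are not inflated by `c-hat`; the factor enters model ranking only.
- Boundary estimates (e.g. p -> 1 with saturated detection) are flagged,
  and their Wald SEs should not be trusted.
- The likelihood treats groups independently; shared-across-group `N`
  (`N(.)`) means equal group sizes, not a pooled total.
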