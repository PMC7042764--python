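# Methods

`birdipm` implements a multi-site integrated population model (IPM) for a
declining migratory songbird monitored by two complementary programs:
annual roadside point counts (routes surveyed by identifiable observers)
and constant-effort mist-netting stations yielding individual capture
histories and age-specific capture totals. The model joins the three data
streams at the scale of a small number of breeding strata (genetically or
ecologically defined regions) and links vital rates to climate covariates:
winter drought on the shared wintering range, spring temperature on the
breeding grounds, and tailwind conditions during spring migration.

## Model

### Population process

The stratum population index n_{m,t} is a positive real, not a census: it
is the expected count on an average route. Each year it splits into
survivors and recruits, n_{m,t} = s_{m,t} + g_{m,t}, with
truncated-Gaussian transitions that match the first two moments of the
underlying demographic processes:

    s_{m,t} ~ Normal[0,∞)( n_{m,t-1} φ_{m,t-1},  n_{m,t-1} φ_{m,t-1}(1-φ_{m,t-1}) )
    g_{m,t} ~ Normal[0,∞)( n_{m,t-1} γ_{m,t-1},  n_{m,t-1} γ_{m,t-1} )

i.e. the moments of Binomial survival and Poisson recruitment. A
continuous index is what allows count and capture-recapture data collected
on different site sets to be joined at a common regional scale; the
truncation at zero is handled with the full normalizing constant so the
density remains proper when the index is small. Recruitment decomposes as
γ = RI × ι: a productivity index RI (expected proportion of hatch-year
birds among aged captures) times a latent multiplier ι absorbing
first-year survival and immigration. ι is deliberately latent — no data
stream measures it directly — and is year- and stratum-specific.

The second argument of the transition normals is a **variance** (the
Binomial/Poisson moments); prior notations below follow the precision
convention of the BUGS-family software this model class is usually fitted
with. The two conventions coexist in the source literature of this model
family; the variance reading is the only dimensionally sensible one for
the process, so it is fixed here and not configurable.

### Count observation model

Counts on route×observer unit i are overdispersed Poisson around the
stratum index:

    y_{i,m,t} ~ Poisson(exp(log n_{m,t} + ω_i + η I(i,t) + ε_{i,m,t}))

with ω_i ~ N(0, σ_ω²) a route×observer random effect, η a single global
novice (start-up-year) effect with indicator I, and ε ~ N(0, σ_ε²)
per-cell overdispersion (one σ_ε shared across strata, following the
established hierarchical count model this component replicates). Missing
(i,t) cells are simply absent from the likelihood (unbalanced panel). The
route-level abundance index applies the lognormal mean correction

    N_{m,t} = w_m exp(log n_{m,t} + σ_ω²/2 + σ_ε²/2)

with w_m the proportion of physical routes in the stratum on which the
species was ever encountered. Trends are geometric means of N_{t+1}/N_t,
reported as 100(λ̄−1) %/year; composite abundance and trend weight strata
by the proportion of range area they cover (a reporting input, not an
estimated quantity).

### Transient Cormack–Jolly–Seber model

Newly marked adults are residents with probability π_{m,t} (logit-linear:
stratum intercept + year effects); transients are never re-encountered.
Residents follow the standard CJS absorbing-death chain with apparent
survival φ_{m,t} and recapture probability p constant over time but
heterogeneous across stations (logit p = stratum intercept + station
random effect, sd σ_p shared across strata; station heterogeneity is the
dominant effort signal in constant-effort banding data, and year-varying p
was left out for parsimony). The within-season residency observation r is
scored only in the marking year, with P(r=1 | resident) = ρ_m and
P(r=1 | transient) = 0; how r is derived from raw within-season records is
the data provider's concern.

Both latent states (residency R, alive z) are marginalized in closed form.
With constant within-individual p, a history is summarized by
(first, last, #recaptures, #misses) and the resident likelihood is

    ∏_{t=first}^{last-1} φ_t · p^ncap (1-p)^nmiss · χ_last,
    χ_t = (1-φ_t) + φ_t (1-p) χ_{t+1},

with the transient branch (1−π)·1{no recaptures, r=0} added. This is
algebraically identical to the forward recursion over z (verified against
exhaustive latent-state enumeration in the tests) but lets thousands of
individuals collapse to a few hundred sufficient-statistic classes.

### Productivity model

Hatch-year counts among aged captures at a station-year are Binomial with
logit-linear success probability: stratum intercept α0_m, centred
log(net-hours) effort term (coefficient α_ef, global), winter-drought and
spring-temperature terms (α_cmd, α_temp, per stratum), year random effects
(sd σ_yr per stratum) and station random effects (sd σ_sta, global).
RI_{m,t} is the fitted hatch-year proportion at reference effort and
average station. Cells with zero aged captures contribute nothing.

### Covariates

* **cmd** — winter (Dec–Feb) climate moisture deficit anomaly: per point,
  Σ_months max(0, Eref − precip); seasonal anomaly = mean over points of
  (annual − 1961–1990 normal). Per-month clamping at zero is the
  conventional deficit definition (a wet month cannot repay a dry one);
  the unclamped signed sum is available behind a flag. The winter labelled
  year t spans Dec t−1 … Feb t and predicts survival over the interval
  *ending* at breeding season t (drought precedes spring arrival), so the
  survival interval t→t+1 uses the covariates labelled t+1.
* **temp** — spring (Feb–May) breeding-ground temperature anomaly.
* **tw** — mean tailwind: wind vector projected on the migration bearing
  (u sinθ + v cosθ), flat-averaged over grid points, the 800 and 950 mb
  levels with equal weight (the source data give no reason to weight
  them), and all 6-hourly samples in the stratum's migration window except
  the midday sample (songbirds migrate at night and around dawn/dusk).
  Bearings and windows are configuration inputs.

Covariates enter the vital-rate models z-scored within stratum (population
sd), which makes coefficients comparable across strata and stabilizes the
sampler; the (mean, sd) record is stored and every fitted coefficient is
also reported per anomaly unit (`*_anom` rows of the summary), which is
the scale recovery tests compare against.

### Priors

Probability-scale intercepts (φ0, π0, p0, ρ, inverse-logit α0) are
Uniform(0,1); regression coefficients and η are Normal(0, variance 1000);
all sd hyperparameters are Uniform(0,10); ι has a truncated
Normal(1, sd 10) prior on [0,∞). The stated source for this model family
writes the ι prior as Norm(1,100) in the precision convention, which would
mean sd 0.1 — but its own recruitment estimates (γ up to ~0.5 with RI near
0.2) require ι well above 1, so the weakly-informative sd-10 reading is
adopted as the default and sd 0.1 is selectable (`PriorSpec.iota_sd`) for
sensitivity runs. Initial states s_1, g_1 get truncated-Normal priors
centred at half the stratum's mean first-year count with sd ten times that
mean (fallback mean 1, sd 10 when first-year counts are all zero); the
exact form of this prior is a package decision — the data dominate it at
any realistic count level.

## Inference

No gradient/autodiff backend is assumed: the sampler is an adaptive
blocked random-walk Metropolis scheme written for this model's structure.

* All hierarchical effects are parameterized **non-centred** (standard
  normal raw effects scaled by their sd), so the sd hyperparameters mix
  through the likelihood instead of through a funnel.
* Structural parameters are grouped into per-stratum blocks (latent
  states; survival intercept+coefficients+year effects; residency;
  recapture; productivity; ι; sd hyperparameters) plus three global blocks
  (count observation, productivity effort/station-sd, recapture
  station-sd). Each block uses multivariate-normal proposals whose
  covariance is the regularized empirical covariance of the chain's
  history (Haario-style) and whose scale is tuned by Robbins–Monro to a
  0.234–0.44 acceptance target. Adaptation runs during the adaptive and
  burn-in phases and is frozen for retained draws, so the recorded chains
  target the exact posterior.
* Unit-level random effects — ω per route×observer, ε per count cell, and
  the two station-effect families — are conditionally independent across
  units given everything else. They are updated by vectorized single-site
  Metropolis moves: one proposal per unit, evaluated in a single pass over
  the data, accepted per unit, with per-coordinate adapted scales. A full
  sweep therefore costs a small constant number of passes over the data
  (~5 ms at the reduced scale, ~28 ms at program scale).

Convergence uses the split-chain potential scale reduction factor with the
conventional < 1.1 threshold, computed per scalar parameter (unit-level
raw effects can be included on request); the implementation is verified to
1e-8 against the `arviz` split-R̂.

A further move targets the model's one structurally slow direction: the
survivor/recruit split s/n is informed only by the process transitions
(the counts see only n = s + g), so a dedicated Metropolis move perturbs
the split's log-odds while holding n fixed — the count likelihood is
invariant under it, and the (log s, log g) → (log n, log-odds) map has
unit Jacobian determinant, so the symmetric step needs no correction.

`MCMCSettings.paper()` preserves the conventional Gibbs-run lengths of
this model family (4 chains, 40k adaptation, 20k burn-in, 80k retained,
thin 4) as a preset of iteration counts; `MCMCSettings.reduced()`
(2 chains, 3.5k adaptation, 1.2k burn-in, 5k retained) is sized for the
desk-scale synthetic scenario, where a fit takes under two minutes on one
core. At those lengths the structural parameters (intercepts,
coefficients, sd hyperparameters) are well mixed; a few year-effect and
latent-state coordinates can retain split-R̂ in the 1.3–1.9 range, which
is why the recovery tests are judged on credible-interval coverage of the
structural truths rather than on a blanket R̂ pass.

## Transient LTRE

The decomposition operates on the **expected** growth scale
λ_t = φ_t + RI_t ι_t (the process-model growth); realized growth from the
abundance index is carried alongside for reporting. For the bilinear λ the
first-order variance decomposition with sensitivities at temporal means
(s_φ = 1, s_RI = ῑ, s_ι = R̄I) assigns each rate Σ_θ' cov(θ,θ') s_θ s_θ',
with the unallocated remainder reported as a residual; per-interval change
contributions use midpoint co-factors (C_RI = ι_mid ΔRI,
C_ι = RI_mid Δι), which splits the ΔRI·Δι cross term equally and makes the
change decomposition exact to machine precision. Both are computed per
posterior draw and then summarized, so the credible intervals on
contributions propagate parameter uncertainty. Age-structure contributions
are omitted: in this model class they contribute essentially nothing, and
the two-term structure (survivors + recruits) leaves no further structure
to decompose.

A caveat the decomposition inherits from the model: ι is informed only
through the count data's recruitment residuals, so "recruitment
contribution" partly absorbs sampling discrepancies between the count and
banding site networks. The synthetic generator reproduces this situation
(ι truly variable, φ stable), and the program-scale test checks only the
qualitative ranking — recruitment components above adult survival — not
ι's magnitude.

## Synthetic data

The generator simulates **discrete** demography — integer populations,
Binomial survivors, Poisson recruits, individual Bernoulli capture
processes — while the fitted model uses the Gaussian approximation. Tests
that fit generated data therefore quantify the approximation error the
model actually incurs rather than testing the model against itself.
Emulated features: transients among newly marked birds, station
heterogeneity in recapture and productivity, observer turnover with
geometric tenures and novice first-year effects, lognormal overdispersion
in counts, lognormal station effort driving both the number of aged
captures and (through the effort coefficient) the hatch-year fraction, and
optionally AR(1) climate anomaly series. What it does **not** emulate:
spatial structure within strata, density dependence, trends in effort or
coverage, misclassification of age or residency, and count–banding site
overlap. Passing recovery tests therefore demonstrates correctness of the
inference machinery under the model's own assumptions plus the
discrete/continuous mismatch — not robustness to the further realities of
field data.

Two presets:

* `reduced` — 1 stratum, 40 routes, 25 stations, 17 years; truth φ0 =
  0.47, β_cmd = −0.2, β_tw = 0, σ_ν = 0.17, α_temp = 0.27, σ_yr = 0.3,
  RI intercept 0.21, π0 = 0.6, p0 = 0.35, ρ = 0.7, ι̅ = 2.5 (lognormal,
  log-sd 0.2), η = −0.3, σ_ω = 0.4, σ_ε = 0.25, initial population 400 at
  a route scaling of 50 (mean count ≈ 8/route).
* `table1` — 3 strata at the monitoring programs' magnitudes (148/58/21
  routes, 66/26/15 stations, 17 years), truth patterned on the fitted
  multi-stratum estimates: φ0 = (0.45, 0.50, 0.49) with drought effects
  (0, −0.17, −0.23), productivity intercepts (0.21, 0.10, 0.23) with
  temperature effects (0.28, 0.26, 0.06), σ_yr = (0.25, 0.42, 0.40), and a
  strongly variable ι (log-sd 0.35) whose stratum means (2.5, 5.2, 2.2)
  balance γ = λ − φ at the reported trends (−2.5, +2.3, −0.7 %/year).
  Marking and aged-capture rates per station-year reproduce the programs'
  individual and recapture totals to well within a factor of 1.5;
  recapture probabilities (0.30, 0.30, 0.18) are calibrated to the
  per-individual recapture fractions of the three regional datasets.

Generation is bit-reproducible given (scenario, seed), and every generated
dataset passes the full input validation.

## Numerical choices and scaled-down problem sizes

* Truncated-normal log-densities are computed with `log_ndtr` for the
  normalizing constant; probabilities inside the CJS machinery are clipped
  to [1e-12, 1−1e-12] before logs.
* Total variation distances between the truncated-Gaussian approximations
  and the exact Binomial/Poisson laws are computed on integer bins
  ([k−½, k+½) ∩ [0,∞), with mass beyond the support charged to the
  distance) using the standard TV definition (half the L1 distance).
* The recovery experiment in the test suite runs 5 replicates of the
  reduced scenario with the short-chain preset and requires 95% credible
  intervals to cover each truth in ≥ 4/5 replicates (an 80% rate) with
  |mean bias(φ̂0)| < 0.03; the program-scale LTRE ranking check runs one
  short-chain fit of the `table1` scenario. These problem sizes are the
  package's chosen desk-scale defaults; the same machinery runs the full
  `paper` preset unchanged.

## Known limitations

* Random-walk MCMC mixes slowly when the posterior is dominated by the
  process prior (e.g. data-free runs with a large population index); the
  prior-predictive test uses a near-zero index for this reason.
* ι is weakly identified by construction; its posterior leans on the
  truncated-Normal prior when count data are sparse.
* p is time-constant within station; year-varying recapture would need an
  extension of the sufficient-statistic compression (per-year capture
  indicator counts), which the class structure supports but the package
  does not implement.
* Quantitative estimates for real monitoring data (actual stratum trends
  and covariate effects) require the field datasets themselves, which the
  package reads but does not ship; `scripts/acceptance.py` instead checks
  exactness, calibration and qualitative structure on synthetic data.
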