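# Methods

## Model

`mtcni` implements an arm-based Bayesian hierarchical model for mixed
treatment comparisons of aggregate (arm-level) trial data. Every study *s*
receives an additive effect α_s drawn from a common Normal distribution
α_s ~ N(μ, τ²); every treatment regimen *t* an absolute effect θ_t with an
independent proper N(0, 100²) prior; covariate coefficients β_k get
N(0, 10²) priors; the hyperpriors are μ ~ N(0, 10²) and
τ² ~ Inverse-Gamma(0.001, 0.001).

Two likelihood families cover the three COPD endpoints:

- **Normal** (change from baseline FEV₁, litres; SGRQ Total score, units):
  the reported arm mean change is modelled as
  Y ~ N(α_s + θ_t + β·Z, s²). In the default `reported_se` variance mode
  s² is the arm's squared reported standard error, treated as known — the
  standard treatment of aggregate data, where the within-arm sampling
  variance is published. A `shared_sigma` mode instead estimates a single
  residual variance σ² ~ IG(0.001, 0.001) across arms. Both are exposed
  because a single shared observation variance and per-arm known variances
  are both defensible readings of aggregate reports; results for
  well-reported data are insensitive to the choice, and `reported_se` is
  the default because it uses the information the trials actually publish.

- **Poisson** (moderate/severe exacerbations): the arm's event count is
  modelled as Exac ~ Poisson(person_years · rate) with
  log(rate) = α_s + θ_t + β·Z. Person-years are reconstructed as
  events/rate when both are reported, passed through when reported
  directly, and otherwise computed as (duration_weeks / 52) ×
  (completers + 0.5 × withdrawals): completers contribute full follow-up,
  withdrawals half of their potential follow-up. When only a rate is
  reported the count is round(rate × person-years), half away from zero,
  because the Poisson likelihood needs an integer; the induced rate error
  is at most 0.5/person-years.

### Identifiability

The likelihood is invariant under θ_t → θ_t + c, α_s → α_s − c: only
contrasts θ_t − θ_t′ are likelihood-identified, and all reported summaries
are contrasts (mean differences or rate ratios). The proper priors pin the
absolute level and keep the posterior integrable even on disconnected
networks — which is why disconnection is a reported warning plus an
explicit `allow_disconnected` override rather than an error: contrasts
across components are prior-driven and should be read as such.

### Covariates

The full covariate set comprises arm-level mean age (centred at 60 years),
proportion male (centred at 0.75), proportion current smokers (centred at
0.5), and indicators for % predicted FEV₁ band (<50 / 50–70 reference /
>70, band boundaries assigned to the reference), exacerbation history
(≥1 reference / ≥2 / not reported) and study-duration band (<20 / 20–40 /
40–60 reference / >60 weeks, the reference closed on both ends, interior
cuts half-open on the left; bands configurable). A missing covariate is
imputed to the reference (centred value 0, indicators 0) with a logged
flag, so it contributes no covariate effect; dropping incomplete studies
instead would break evidence networks. A reduced `duration_only` set and
`none` are available for sensitivity analyses. One year is 52 weeks
exactly throughout.

## Sampling

Posterior draws come from a Metropolis-within-Gibbs scheme:

- conjugate Gibbs updates for μ and τ² (Normal–Inverse-Gamma), and in the
  normal family for the study effects α_s and (in `shared_sigma` mode) σ²;
- scalar Gaussian random-walk Metropolis updates for every θ_t and β_k,
  and for α_s in the Poisson family;
- one symmetric random-walk move along the likelihood-flat translation
  direction (θ + c, α − c, μ − c), whose acceptance ratio involves only the
  priors. Without it the weakly identified common level is the slowest
  direction of the chain (split-Rhat ≈ 1.9 on short Poisson runs, ≈ 1.03
  with it); contrasts are orthogonal to this direction, but μ and the
  individual θ_t mix far better with the move.

Step sizes adapt per parameter towards 0.44 acceptance (the standard
target for scalar updates) in windows of 50 iterations during burn-in
only, with a decaying adaptation rate; after burn-in the steps freeze, so
retained draws come from a fixed Markov kernel and the stored step-size
trajectory certifies it. Defaults are 4 chains, 10 000 burn-in and 40 000
retained draws — deliberately generous for routine analyses; the test
suite and acceptance script use shorter, explicitly stated runs sized to
their toy problems. Initial values are data-informed (study effects at
crude study means or log crude rates, θ = β = 0, variances at 0.1); one
master seed spawns independent per-chain streams, and a fixed seed
reproduces chains bit for bit.

Diagnostics report split-Rhat and effective sample size (via ArviZ) for
every θ_t, contrasts against the first treatment, μ and τ², plus
acceptance rates flagged outside [0.15, 0.6]; Rhat > 1.1 on a monitored
quantity raises a convergence warning in the run manifest.

### Validation oracles

Two independent routes validate the sampler in the tests and acceptance
script, never in analyses: closed-form conjugate posteriors on pinned-toy
problems, and `grid_posterior_oracle`, which integrates the same
log-posterior by direct summation over a bounded grid of at most three
free parameters and refuses grids holding more than 1% of mass on their
boundary.

## Reported summaries

Contrasts are summarised by their posterior mean, median and equal-tailed
95% percentile interval (not HPD), on the mean-difference scale for
continuous endpoints and the rate-ratio scale exp(δ) for exacerbations.
Non-inferiority probabilities follow per-endpoint direction conventions —
FEV₁ higher-better: P(δ > −m) with m = 0.05 L; SGRQ lower-better:
P(δ < +m) with m = 2 and 3 units; exacerbation rate ratios:
P(RR < 1 + m) with m = 0.10 and 0.20. The probability is monotone
non-decreasing in the margin by construction. Human-readable output
reports ">99%" above 0.99, machine output full precision. Placebo-referenced
tables report θ_t − θ_placebo (or exp of it, with the placebo row
identically 1.0).

Standardized residuals are (posterior-mean fitted value − observed) /
estimated sd, the sd being the observation sd the likelihood used
(reported SE; posterior mean √σ²; or √fitted-count on the count scale).
Because the posterior-mean fit absorbs part of the observation noise
whenever study effects are freely estimated — a study effect fitted to two
or three arms tracks their average — these residuals are *conservative*:
on data simulated from the model itself the share of |z| > 2 is well below
the nominal 5% (≈0.5–1% on the default 28-study network). The nominal rate
is recovered when the study-effect block is pinned at its generative value
(a supported sampler mode used by the calibration tests), up to the small
(1 − 1/m) variance deflation from estimating the treatment effects.
Residual counts should therefore be read as a lack-of-fit screen, not a
calibrated error rate.

## Synthetic data

The generator draws datasets from exactly the structure the model assumes:
α_s ~ N(μ*, τ*²); per-arm covariates (age ~ N(63.79, 5²); proportions male
and current smokers Beta-distributed around 0.73 and 0.46 with
concentration 40 — centres matching the evidence base the model targets);
per-study severity and exacerbation-history categories; Binomial(n, 0.10)
withdrawals with uniform timing consistent with the half-follow-up rule;
Normal arm means with standard errors derived from an assumed
subject-level sd (0.25 L for FEV₁, 12 units for SGRQ — aggregate reports
carry no subject-level dispersion, so these are explicit scenario knobs)
divided by √n; and Poisson counts over the implied person-years. Every
simulated dataset round-trips through the CSV dialect, and a truth sidecar
records all latent values for recovery and coverage studies.

`make_copd_network` provides three ready topologies: a 28-study FEV₁
network (8 regimens, FF/VI linked by head-to-head, three-arm and
monotherapy studies; true FF/VI − FP/SAL contrast +0.023 L, τ* = 0.02 L),
a 15-study exacerbation network in which a single 12-week FF/VI study —
also the only study under 20 weeks — bridges the FF/VI cluster to the rest
(placebo rate 1/year, active rate ratios 0.62–0.90, τ* = 0.10, with age
and short-duration covariate effects), plus 6 optional studies without an
explicit exacerbation-history requirement for sensitivity filters, and a
20-study SGRQ network (placebo-referenced effects −4.6 / −3.3 / −3.6
units, τ* = 0.5).

What the generator does *not* emulate: real extraction error, outcome
definition heterogeneity across trials, correlated covariates, informative
withdrawal, non-Poisson overdispersion of exacerbations, or reporting
selection. Passing recovery and coverage tests therefore certifies the
pipeline's internal consistency (the fit inverts the stated generative
process), not robustness to those real-data departures — which is exactly
what the sensitivity filters and residual screens exist to probe on real
inputs.

## Numerical choices and limitations

- Inverse-Gamma draws use τ² = rate_post / Gamma(shape_post); support
  violations (τ² ≤ 0) score −∞ rather than raising.
- Log-likelihoods include all constants (Normal normalisers, log-factorials)
  so values are comparable across variance modes and usable by the grid
  oracle.
- Event-count rounding is half away from zero; the grid oracle's boundary
  tolerance is 1%; credible intervals are percentile-based; ties in grid
  symmetry checks carry one grid-step of mass.
- Replicated experiments in the tests and acceptance script use 1–2 chains
  of a few thousand iterations on the 28-study network — sized so that
  MCMC error is several times smaller than the posterior spread being
  measured — and state their sizes explicitly.
- The model assumes treatment effects are exchangeable across studies
  (no treatment-by-study interaction) and covariate effects shared across
  treatments; contrast-based parameterisations and ranking statistics
  (e.g. SUCRA) are out of scope.
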