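# Methods

`sightabund` estimates animal abundance from stratified aerial surveys in
which detection is imperfect and detection probability depends on visual
obstruction. It implements the two estimation traditions used for such
surveys — a design-based expansion estimator and a family of data-augmented
hierarchical Bayesian models — together with the survey simulator used to
validate both.

## The observation system

Two kinds of data exist. **Sightability trials** overfly plots containing
radiocollared animal groups; missed groups are recovered by telemetry, so each
trial record carries a detection indicator `z ∈ {0,1}` and the group's visual
obstruction `x ∈ [0,1]` (the proportion of screening cover near the first
animal seen). **Operational surveys** are detection-only: a stratified random
sample of plots is flown each winter and only the groups actually seen are
recorded (group size `y ≥ 1`, obstruction `x`, plot, stratum, year). The
survey design table gives, per stratum `h` and year `t`, the total plot count
`N_ht`, the sampled count `n_ht`, and the plot inclusion probability
`π_ht = n_ht / N_ht`.

The sightability model is a logistic regression

    logit(g) = β0g + β1g · x

fit to the trial data only. Obstruction is the single covariate.

## Design-based estimation (mHT)

The modified Horvitz–Thompson estimator expands each detected group by an
inflation factor θ̂ and the plot inclusion probability:

    τ̂_t = Σ_h Σ_i Σ_j  y_hijt · θ̂_hijt / π_hit

θ̂ uses the lognormal bias-corrected form
`θ̂ = 1 + exp(−β̂0g − β̂1g x − x̃'Σ̂x̃/2)` with `x̃ = (1, x)` and Σ̂ the MLE
covariance; under β̂ ~ N(β, Σ) this makes `E[θ̂ − 1] = exp(−x'β) = 1/g − 1`,
so θ̂ is an unbiased estimate of the reciprocal detection probability.

The variance estimator has three components:

1. **plot sampling** — for each stratum, `N(N−n)/n · S²`, where `S²` is the
   between-plot sample variance of estimated plot totals with the mean
   within-plot detection variance subtracted, so detection noise is not
   counted twice;
2. **detection** — `Σ y² θ̂ (θ̂−1) / π²` over detected groups, the
   plug-in estimate of the Bernoulli-thinning variance;
3. **detection parameters** — `Σ_jk (y_j/π_j)(y_k/π_k) Ĉov(θ̂_j, θ̂_k)` with
   the lognormal plug-in `Ĉov = (θ̂_j−1)(θ̂_k−1)(exp(x̃_j'Σ̂x̃_k) − 1)`;
   because all groups share one fitted curve this sums over all pairs,
   across strata.

Confidence intervals are lognormal, `τ̂/C` to `τ̂·C` with
`C = exp(z_{1−α/2} √ln(1 + var/τ̂²))`, at `α = 0.10`. The estimator is
validated by simulation: over 500 replicate surveys from the generator the
mean estimate is within a few percent of truth and the 90% interval covers
truth at close to the nominal rate (the acceptance script recomputes both).

## The hierarchical models

Each sampled plot in stratum `h` is padded to `B_h` candidate group records
(data augmentation, defaults `B_h = 40/60/100` for strata 1–3), fixing the
dimension of the latent space. Record `j` in plot `i` carries

    q ~ Bernoulli(ψ_hit)            presence
    y − 1 ~ Poisson(λ_ht)           group size (shifted Poisson, y ≥ 1)
    x ~ Beta(a_x, b_x)              obstruction
    z | x, q ~ Bernoulli(g(x) · q)  detection

with `ψ_hit ~ Beta(a_ψ, b_ψ)` per plot. Both Beta distributions use the
mean/concentration parameterization `a = μρ`, `b = ρ − μρ` with hyperpriors
`μ ~ Uniform(0.01, 0.99)` and `ρ ~ N(5, 1)` truncated to `(0.01, 10)`;
`log λ ~ N(0, 3.16)`. Normal scales are standard deviations throughout
(3.16 ≈ √10 is the conventional vague logit-scale sd; the same convention is
applied to the N(0, 5) spline-coefficient priors). Yearly abundance is the
posterior(-predictive) sum `τ_t = Σ y·q` over all plots, with unsampled plots
drawn fresh from the current parameters at every retained iteration.

**FE model** — every parameter except the detection curve is year- and
stratum-specific; years are independent given the detection curve.

**TS model** — two forms of temporal smoothing: exchangeable random effects
on the group-size rate, `log λ_ht = μ_h + δ_ht`, `δ_ht ~ N(0, σ_h²)`,
`σ_h ~ Uniform(0, 3)`, `μ_h ~ N(0, 3.16)`; and a natural cubic spline (3
degrees of freedom) with stratum-specific intercepts on the yearly mean
presence probability, `logit(μ^ψ_ht) = Xβ^ψ`, `β^ψ ~ N(0, 5)`. The
concentration ρ^ψ keeps its year-specific truncated-normal prior, and the
obstruction-distribution parameters remain year-specific fixed effects, so
annual shifts in where animals sit on the landscape stay unrestricted.

**Joint model** — the FE structure with the detection parameters sampled
inside the chain, informed by trials *and* operational data. This is the
specification whose detection curve is known to drift as detection-only data
accumulate; it is retained for the sensitivity diagnostic.

### Spline basis

The spline module builds the truncated-power natural cubic basis (linear
beyond the boundary knots, interior knots at the `k/(K+1)` quantiles of the
year grid by default, or supplied explicitly, e.g. `--knots 2010,2014`).
B-spline and truncated-power representations of the same knot set differ by
an invertible linear map, so fits are identical; tests verify fit-equivalence
against a reference `ns()` basis rather than column equality. Inside the
sampler the basis columns are centered and scaled over the year grid: the
stratum dummies span the intercept, so the column space — and hence the
model — is unchanged, while coefficients stay O(1), which conditions the
random-walk updates and makes the vague prior act symmetrically.

### Two-step (cut-posterior) fitting

To keep the detection curve informed only by the trials, the posterior is
factorized as `[Θ, Φ | Y, Z] ∝ [Y | Θ, Φ] [Φ | Z] [Θ]` and sampled in two
stages: (1) MCMC on `[Φ | Z]` (defaults: 2 chains × 10,000 iterations,
burn-in 3,000, thin 2 → 7,000 draws); (2) `s = 75` draws selected uniformly
without replacement; (3) for each draw, the hierarchical sampler runs with Φ
fixed as data (2 chains × 3,000, burn-in 2,000, thin 2); (4) all retained
draws are pooled (75,000 with the defaults; `pool_mode="last"` keeps only
each chain's final state for large-`s` runs). By construction the pooled Φ
marginal equals `[Φ | Z]`; a Kolmogorov–Smirnov comparison against an
independent trials-only run checks the implementation.

### Sampler details

Inference is Metropolis-within-Gibbs, vectorized over the records of each
stratum-year block:

* `q` for augmented records: conjugate Bernoulli with odds
  `ψ(1−g(x)) : (1−ψ)`;
* `ψ` per plot: conjugate Beta(a + Σq, b + B − Σq);
* latent `x` for present-but-undetected records: independence Metropolis
  with the Beta marginal as proposal and acceptance ratio
  `(1−g(x'))/(1−g(x))`;
* all block-level parameters: adaptive Gaussian random walks on
  unconstrained transforms (log for rates, scaled logit for interval-bounded
  parameters), step sizes tuned toward ~40% acceptance during burn-in and
  frozen afterwards; the 6-dimensional spline block and the detection pair in
  the joint model use multivariate random walks with adapted covariance;
* latent draws that carry no likelihood terms — group sizes of augmented
  records and obstruction of absent records — are redrawn from their
  conditionals after the parameter updates. The parameter moves are thereby
  partially collapsed (the group-size rate conditions on observed sizes only;
  the obstruction-distribution parameters condition on observed plus
  present-augmented `x`), a blocked Gibbs scheme with the same target as the
  fully explicit sweep but much faster mixing;
* block-level updates are repeated a few times per sweep (`hyper_reps`,
  default 3): they cost little next to the latent-record updates and mix
  slowest.

Chains are initialized from prior means with observed-data moment matching
for the group-size rate and the obstruction mean (with multiplicative jitter
when multiple chains run). Convergence is monitored with the potential scale
reduction factor on all top-level parameters, flagged at R̂ ≥ 1.1. R̂ is
computed as the square root of pooled variance over mean within-chain
variance (population-variance convention); this form is exactly 1 for
identical chains, is always ≥ 1, and agrees with the classic
between/within form asymptotically.

Beta draws are clipped to `(1e−12, 1 − 1e−12)` before log-density
evaluation; support violations during Metropolis return −∞ (rejection)
rather than raising.

## The simulator

The generator emulates the three-stratum winter moose design: stratified
random plot sampling without replacement at fractions 0.06/0.11/0.20 of
strata 1/2/3 (`n = max(1, round(fraction·N))`), Beta-distributed obstruction,
shifted-Poisson group sizes, logistic detection, and the same
augmentation-style population construction the models assume (`B_h`
candidates per plot, present with plot-level Beta-Bernoulli probability).
Default truth: `B_h = (40, 60, 100)`, detection curve `(0.33, −0.99)`,
obstruction mean 0.4 (concentration 4), presence means `(0.08, 0.15, 0.25)`
rising with stratum density, group-size rates `(1.0, 1.5, 2.0)` so mean group
sizes run 2–3 animals, and 124 sightability trials. The trial obstruction
distribution is Beta(2, 3); the distribution used in the historical trials is
not recorded, so this is a package choice, exposed via `x_distribution`.
Obstruction is drawn once per group and is the same whether or not the group
is detected. A group's truth status never depends on the detection
parameters, and all tables are reproducible bit-for-bit from the config seed
through per-table substreams.

What the generator does **not** emulate: spatial covariates or
autocorrelation between plots, animal movement between plots (closure is
assumed), stratum reassignment between years, observer effects, and any
misspecification of the obstruction or group-size laws. Passing recovery
tests therefore demonstrates internal consistency of estimator and sampler
under the assumed model, not robustness to the ways real surveys violate it.

## Scales used in the shipped checks

The automated checks run on one CPU, so simulations are scaled to desk size
as a package design choice: the mHT calibration uses 500 one-year surveys
with `N = (100, 60, 40)` plots; parameter recovery uses nine replicate
six-year surveys with 40 plots per stratum and a reduced two-step fit
(`s = 10`, 2 chains × 500 iterations); the cut-posterior check uses a
micro-survey with `s = 2500` and heavily thinned step-1 chains; the
sensitivity diagnostic uses deliberately small surveys (`B_h = (6, 9, 12)`)
so each added year of detection-only data shifts the joint posterior
appreciably relative to the 124 trials. The drift scenario gives the trials a
*rising* detection curve: the direction in which the augmented operational
mass pulls the slope (downward, through zero) is then unambiguous, which
makes the monotone drift of the joint model — and the exact invariance of the
two-step fit — cleanly testable.

## Known limitations

* The q/x/ψ latent structure is weakly identified at very small survey
  sizes; posteriors then lean on the hyperpriors, and the joint model can
  equilibrate far from the trial-only detection curve (this is the
  phenomenon the two-step fit exists to prevent, and the package's joint
  model exhibits it by design).
* The mHT variance is a plug-in estimator; its model component assumes
  approximate normality of the fitted detection coefficients.
* Group sizes support shifted-Poisson only; negative-binomial or truncated
  alternatives are out of scope.
* No spatial structure; plots are exchangeable within stratum and year.
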