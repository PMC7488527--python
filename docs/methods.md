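# Methods

## The estimation problem

A beetle cohort develops through an ordered sequence of twelve stages.
The first nine (early cleavages through boring into the seed) can only be
observed destructively: a sample of eggs laid within a short collection
window is incubated at constant temperature and sacrificed at age *t*,
yielding a binomial count — how many of the *n* individuals are at or past
a given stage boundary. The last three (larva, pupa, teneral adult) are
followed per individual through an incision in the seed coat, yielding one
duration per stage per beetle, plus adult mass and sex.

## Transition times from counts

For each stage boundary and temperature the proportion past the boundary
is modelled as a logistic function of age,

    logit P(t) = β₀ + β₁ t,      t₅₀ = −β₀/β₁,

with each sample entering the likelihood as Binomial(nᵢ, P(tᵢ)). Ages are
centered and scaled internally; coefficients are reported on the hour
scale. Newton/IRLS iterations run to a score norm below 1e−8 (at most 100
iterations, with step halving so the objective never decreases);
convergence failures are flagged, never silent.

Synchronous transitions sampled on a practical grid regularly yield
complete or quasi-complete separation — no sample shows an intermediate
count and a perfect step function splits the data — under which the ML
estimates diverge. Separation is detected both from the data (a
threshold age separating all-zero from all-past samples) and from the
iteration (|β| exceeding 25 on the standardized scale with a
non-vanishing score; the bound is configurable). The bias-reduced
estimator maximizes the Jeffreys-penalized likelihood
ℓ(β) + ½·log det I(β) via IRLS with hat-value-adjusted working counts and
always returns finite estimates; on symmetric separated designs the
penalty places t₅₀ at the midpoint. The `auto` method uses ML where the
data overlap and the penalized fit under separation — in practice that
means penalized fits for the fast embryonic transitions and ML for the
slower, noisier late-larval ones. Replicate samples taken at nearly the
same age are pooled by summing counts within the age rounded to the
nearest hour.

Fits with β₁ ≤ 0 (proportion past not increasing with age) are invalid by
definition of a developmental transition and are rejected when a median
transition time is requested.

## Reaction norms, thresholds, thermal constants

Median stage durations are consecutive differences of t₅₀ along the stage
order (the first stage's duration is its own transition time; durations
must be strictly positive, and they sum exactly to the final transition
time). Rates R = 1/D are regressed on temperature by OLS. The analysis
treats the relationship as linear only when R² ≥ 0.97 (configurable gate);
below the gate the linear coefficients are still reported but flagged, and
a quadratic R = c₂T² + c₁T + c₀ is the recommended provisional
description, its smaller real root (the crossing below the vertex)
standing in for the lower threshold; complex roots are reported as "no
crossing".

For a linear norm, LTT = −a/b and K = 1/b. The LTT is invariant to the
rate unit; K converts as degree-days = degree-hours / 24. Rates carry
explicit unit tags throughout: per-hour for the destructive stages,
per-day for the within-seed stages (mixing the two is the classic way to
mis-state a thermal constant by a factor of 24).

Three approximations of SE(LTT) are provided, because the approximation
used for such data historically is known to be rough: the classic
Campbell-style formula SE = (ȳ/b)·√(s²/(Nȳ²) + (SE_b/b)²), a first-order
delta method on −a/b using the full OLS covariance, and a parametric
residual bootstrap. Delta and bootstrap agree within ~15% on
well-conditioned fits; all three are exactly zero on a perfect line. None
of them has well-understood coverage at N = 5 temperatures, and the
package treats them as descriptive.

The realized chamber temperatures (e.g. 19.8 °C, not the 20 °C set
point) are the regression covariates; set points are kept as regime
labels. The two destructive blocks (pre- vs post-dorsal-closure) ran at
slightly different realized temperatures and are tracked separately.

## Individually resolved stages: heteroskedastic GLS

Per-individual rates (1/duration, day⁻¹) and masses are modelled as

    y = β₀ + β_T·(T − T̄) + β_S·s + β_TS·(T − T̄)·s + ε,

with temperature continuous (centered), s a ±½ sex contrast (female +½,
so β_S is the female-minus-male difference), and Var(εᵢ) = σ²_{stratum(i)}
with one variance per temperature × sex stratum. REML estimation profiles
the fixed effects: weighted least squares given the variances, then each
stratum variance is updated as its residual sum of squares divided by
(n_s − Σ leverages), iterated to a relative change below 1e−8. The fixed
point solves the REML score equations; the implementation reproduces
nlme::gls with a varIdent structure to ~1e−8 on coefficients, standard
errors, REML log-likelihood and F statistics (frozen oracle in the test
suite). Multipliers are reported as variance ratios against the first
stratum in label order.

Inference uses sequential (type I) F-tests in the order temperature, sex,
temperature × sex: nested weighted RSS differences over the full-model
mean square, with the estimated weights held fixed, each on (1, N − 4)
degrees of freedom. Stage summaries (median with quartiles per
temperature) use linear-interpolation quantiles by default (configurable,
since quantile conventions differ across software). Records flagged
discarded/overlooked are excluded with a logged count.

## Scaling diagnostics

Equiproportional development (rate isomorphy) — every stage occupying a
temperature-independent fraction of development — holds exactly when all
stages share one LTT. The package reports the descriptive quantities:
stage durations as fractions of a reference span (e.g. oviposition →
dorsal closure ≡ 1), ratios of spans between transitions, stage-median
ratios (the ratio-of-medians and the median-of-individual-ratios variants
differ and are labelled), and the min/max/range of per-stage LTTs with a
configurable compatibility tolerance (default 1 °C). No formal regression
test of proportions is performed; proportions sum to one and are not
independent observations.

## The cohort simulator

The simulator generates data with the statistical structure the analysis
assumes, with known ground truth:

* each stage s has a thermal law for its median rate — linear
  R_s(T) = a_s + b_s·T or quadratic — and median duration 1/R_s(T);
* individual i's realized duration of stage s is
  D_s(T)·exp(ε_is)·exp(η_i), with ε_is ~ N(0, σ_s) stage-specific
  lognormal noise (σ from a CV via σ = √log(1+CV²), so the median is
  preserved) and η_i an optional lognormal factor shared across all of an
  individual's stages, modelling persistently slow or fast developers
  (default SD 0: the destructive design cannot measure it, so the default
  is the agnostic one);
* oviposition is jittered uniformly over the collection window (default
  20 min) around the recorded midpoint age;
* each scheduled destructive sample draws fresh individuals (destructive
  sampling sacrifices them), computes cumulative transition times as
  running sums of stage durations, and records the count at or past each
  boundary; sample sizes are fixed by default, optionally Poisson;
* within-seed individuals get per-stage durations in days, sexes assigned
  by stratified permutation (the configured ratio holds exactly per
  temperature), and mass from a sex-specific quadratic in temperature
  with Gaussian noise.

Defaults reproduce the reference study conditions: the per-stage fitted
thermal laws (per-hour linear for the nine destructive stages — the two
markedly nonlinear ones get their OLS linear description as simulation
truth; per-day for larva and pupa; quadratic for the teneral stage), the
realized chamber temperatures 19.8–31.7 °C, destructive CV 0.08,
within-seed CVs calibrated from the reference quartile spreads (larva
0.15, pupa 0.12, teneral 0.40 — the teneral stage is by far the most
variable within-seed period), 30 eggs per destructive sample, 115
individuals per temperature, sex ratio 0.5, female masses ~6.95 mg and
male ~5.07 mg at 26 °C with a negative temperature response (stronger and
monotone in females, shallowly U-shaped in males) and SD 0.8 mg. The
default destructive schedule brackets each transition's true median with
samples at 80–120% of it, emulating pilot-then-refine scheduling.

Sex assignment is stratified rather than Bernoulli for a statistical
reason: the teneral law is quadratic while the ANOVA mean model is linear
in temperature, and with randomly imbalanced strata that lack of fit
leaks into the sex contrast and fabricates sex effects. Balanced strata
keep the sex contrast orthogonal to any pure temperature response.

What the simulator does *not* emulate: mortality and infertile eggs,
the long-post-feeding "active form" polyphenism, within-seed competition,
temperature fluctuations, or observational staging error beyond binomial
sampling. Passing recovery tests therefore show that the estimation chain
is correct under the assumed noise model, not that real data meet those
assumptions.

## Numerical choices and test conditions

* Logistic IRLS: score tolerance 1e−8, 100 iterations, separation bound
  25 (standardized scale), step halving; both estimators match an
  independent coarse-to-fine grid maximization of their objectives to
  1e−4 on small datasets.
* GLS: variance-update relative tolerance 1e−8, 200 iterations; a
  stratum variance below ~1e−20 of the response variance indicates an
  exact fit and is equalized rather than amplified; weights are
  normalized to mean one during solves (the common scale is irrelevant)
  and the coefficient covariance rescaled afterwards.
* Pipeline recovery (test conditions): cohorts simulated at the five
  realized temperatures, 50 eggs per sample, destructive CV 0.05; the
  median estimated LTT over 20 seeds is within ±0.5 °C of truth for
  every stage. With zero noise, t₅₀ is only identified up to the
  sampling-grid gap; the estimate lands at the gap midpoint and a dense
  grid shrinks the threshold error accordingly.
* F-test calibration (test conditions): a correctly specified linear
  null with 5 temperatures × 2 sexes, 80 individuals per stratum, 500
  replicates gives an interaction rejection rate of 0.05 ± 0.02.

## Known limitations

* The sequential F-test treats the estimated variance weights as known;
  in small strata it is mildly anti-conservative (the reason the
  calibration run uses strata of 80, comparable to the study's ~57).
* For the teneral stage the linear mean model is genuinely misspecified
  (the true response is curved); its sex-related F-tests remain
  anti-conservative even with balanced strata, and the quadratic
  description should be preferred for that stage.
* LTT standard errors at N = 5 temperatures are rough under every
  implemented method and should not be used for formal cross-stage
  comparisons.
* The LTT is an extrapolation; small shifts in the data points move it
  disproportionately, which is why the linearity gate is strict and the
  quadratic path is labelled provisional.
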