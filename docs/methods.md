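# Methods

This note documents the statistical models, numerical choices and known
limitations of `survcontour`. It is the package's own account of its
science; every empirical claim here is one the test suite or
`scripts/acceptance.py` actually computes.

## The display problem

The package renders the conditional prediction surface of a survival model:
for a designated continuous predictor `x` and any adjusting covariates held
fixed at a profile `z0`, the matrix

    P[i, j] = Ŝ(t_j | x_i, z0)        (or F̂₁(t_j | x_i, z0) under competing risks)

over a covariate grid `x_1 < … < x_m` and a time grid `t_0 = 0 < t_1 < …`.
A 2D colored contour of `P` (time on x, predictor on y, darker = worse
outcome) replaces the usual practice of dichotomizing `x` at the median and
drawing two Kaplan–Meier curves, which discards the continuous information.
A marginal histogram of `x` sits on the shared y-axis so the reader can see
where the data actually live; a 3D rendering adds the pointwise confidence
bands as semitransparent layers.

## Models

### Cox proportional hazards (`fit_cox`, `fit_stratified_cox`)

`h(t|x) = h₀(t) exp(x'β)`, fit by Newton–Raphson on the log partial
likelihood with step-halving. Ties: **Efron** by default (the de-facto
standard of mainstream Cox software), Breslow selectable. Convergence:
relative log-PL change below 1e-9 *and* max |score| below 1e-8·(1+|ℓ|),
capped at 50 iterations. The design is centered for numerical stability;
all reported quantities are mapped back to the raw scale.

The baseline cumulative hazard is the Breslow step estimator

    Λ̂₀(t) = Σ_{t_j ≤ t} d_j / Σ_{i ∈ R(t_j)} exp(x_i'β̂),

used for either ties method (this matches what established implementations
return from their prediction APIs, which is verified in the acceptance
suite). With β̂ = 0 it reduces *exactly* to the Nelson–Aalen estimator.
The stratified model shares β across strata and computes one baseline per
stratum; a stratum without events contributes nothing and is logged.

**Monotone likelihood.** When a covariate perfectly orders the events the
partial likelihood has no interior maximum and β̂ runs away. Detection: if
any |β̂ₖ| exceeds 10 the fitter probes the likelihood 50% further out; if
the score has not vanished or the likelihood is still non-decreasing
outward, an explicit error is raised rather than returning a huge
coefficient that would render a misleading contour. The gradient test alone
is insufficient — under separation the score vanishes *exponentially* as β
grows, so a runaway fit can look "converged"; the outward probe closes that
gap while still admitting a genuine optimum beyond the threshold.

**Prediction variance.** For `Λ̂(t|x) = Λ̂₀(t) e^{x'β̂}`,

    Var[Λ̂(t|x)] = e^{2x'β̂} [ Σ_{t_j≤t} d_j/S₀(t_j)² + Q(t)' V̂ Q(t) ],
    Q(t) = Σ_{t_j≤t} (d_j/S₀(t_j)) (x − x̄(t_j)),

with `x̄(t_j)` the risk-set weighted covariate mean and V̂ the inverse
observed information — the standard asymptotic Cox survival-curve variance,
combining the baseline-increment term with the delta-method term in β̂.
Variances are carried on the `log(−log S)` scale, where they equal
`Var[log Λ̂]`.

### Weibull accelerated failure time (`fit_weibull`)

`S(t|x) = exp(−(t / (λ e^{x'γ}))^k)` — shape `k`, scale `λ`, AFT
coefficients `γ` on log-time. Under proportional hazards the same model has
`β_PH = −k·γ` (exposed as `WeibullFit.beta_ph`). The likelihood is
maximized by BFGS over `(log k, log λ, γ)` with a Nelder–Mead polish if
BFGS stalls; the covariance is the inverse central-difference Hessian at
the optimum.

Censoring modes:

* **right** — events contribute `log f`, censored subjects `log S`;
  requires ≥ 1 event (all-censored data leave the likelihood flat and raise
  an explicit unidentifiability error).
* **interval** — a window `(L, R]` contributes `log[S(L|x) − S(R|x)]` with
  `S(∞) = 0`; exact times (`L = R`) contribute `log f`; requires at least
  one finite window or exact time. This is the only interval-censored model
  offered: the nonparametric Turnbull NPMLE is deliberately out of scope,
  so interval censoring is handled parametrically.

The `log(−log S)` variance for bands is the delta method through
`ψ = k(log t − log λ − x'γ)` with gradient `(ψ, −k, −k·x)` in
`(log k, log λ, γ)`.

### Fine–Gray subdistribution hazard (`fit_fine_gray`)

For competing risks the covariate effect acts directly on the cause-1
cumulative incidence: `F₁(t|x) = 1 − exp(−Λ̂₁₀(t) e^{x'β})`. The
subdistribution risk set at time t keeps subjects who already failed from a
competing cause, weighted by the inverse probability of censoring

    w_i(t) = Ĝ(t−) / Ĝ(T_i−)        (1 while under observation),

where Ĝ is the Kaplan–Meier estimate of the censoring distribution
(left limits, the convention of the reference R implementation — the test
suite pins β̂ against `cmprsk::crr` output to ~1e-6). Fitting is the same
Newton–Raphson with Breslow ties (the IPCW weights have no Efron analogue
here); the baseline uses the weighted Breslow formula.

**Variance approximation.** The covariance is the inverse of the weighted
observed information. This ignores the sampling variability of the weights
and of Ĝ, so it is *not* the full Fine–Gray variance estimator; observed
SEs differ from the sandwich by several percent at n ≈ 100. Simulation
shows ±3 SE recovery coverage ≥ 99% at n = 800, i.e. the approximation is
mildly conservative there. Exact uncertainty is available via bootstrap
bands at the surface level.

With zero competing events every weight is 0 or 1 and the fit coincides
with the Breslow-ties Cox fit to machine precision (asserted at 1e-8).

### External backends (`wrap_backend`)

Spline hazard models, random survival forests and deep survival networks
are not reimplemented. Anything exposing `fit(dataset)` and
`predict_survival(row, time_grid)` can be wrapped; the wrapper clips
predictions to [0, 1] and enforces time-monotonicity (running minimum for
survival, running maximum for incidence), logging any violation. Wrapped
backends produce point surfaces (no analytic bands).

## Surfaces and bands

* Covariate grid: **linear, 100 points over the observed [min, max]** by
  default; quantile spacing and a quantile-trim option exist for
  outlier-dominated axes. No trimming is applied by default.
* Time grid: the sorted unique observed event times with 0 prepended,
  preserving the estimators' exact step structure. An equispaced grid can
  be passed for expensive backend models.
* Adjuster profile: sample **median** for continuous adjusters, **most
  frequent level** for categorical ones (frequency ties broken by sorted
  level order); every entry carries a user/default provenance tag.
* Bands: pointwise, on the `log(−log)` scale (`log(−log S)` for survival,
  `log(−log(1−F))` for incidence), back-transformed — so they always lie in
  (0, 1). Where the estimate is exactly 0 or 1 the band collapses to the
  point. Bootstrap percentile bands (resampled refits, fixed seed,
  degenerate resamples redrawn) are available for any refittable model and
  agree with the delta bands in median width within 30% on n = 500 Cox
  data (tested).
* Hover lookup (`value_at`): step in time (last knot ≤ t, matching the
  step estimators), linear interpolation in the covariate. Queries outside
  the grid raise a range error that names the valid span.

## Rendering

The color contract is **monotone luminance: darker = worse predicted
outcome**. Survival surfaces use a perceptually uniform sequential scale
(viridis) dark→light for low→high survival; cumulative-incidence surfaces
reverse it so high incidence stays dark. Probabilities are binned into
0.05-wide bands by default. The marginal histogram is orange. Hover text
reports probabilities as percentages with one decimal.

Interactive figures are exported as a **single self-contained HTML file**:
the surface and histogram are embedded as a JSON block and the heatmap,
hover readout (same step/linear lookup as `value_at`) and 3D drag-rotation
are inline canvas JavaScript, with no network fetches. The 3D payload is
subsampled to ≤ 60 grid points per axis to keep rotation fluid; the static
3D figure and the 2D exports use the full grid. Static PNG/SVG exports use
matplotlib; SVG output is byte-deterministic (fixed hash salt, timestamps
suppressed).

## Guidance and metrics

The model recommendation walks the guided workflow: competing risks →
Fine–Gray; interval censoring → interval Weibull; otherwise the preferred
family (parametric → Weibull; nonparametric → spline backend, flagged as
backend-required; semiparametric or unsure → Cox, refined to stratified
Cox when the baseline should differ across groups). Competing risks
*together with* interval censoring is an explicit unsupported-combination
error. The branch structure is reconstructed from the workflow's prose
description, gates first, family second, stratification last.

* **Concordance**: Harrell's C — comparable pairs are (earlier observed
  event, longer-observed subject); score ties count ½; no comparable pairs
  is an explicit error. Uno's IPCW variant is not implemented.
* **Integrated Brier score**: `BS(t)` is the IPCW-weighted mean of
  `(1{T_i > t} − Ŝ(t|x_i))²` with weights `1/Ĝ(T_i−)` for past events and
  `1/Ĝ(t)` for subjects still at risk; IBS is the trapezoidal time-average
  over the window. If Ĝ hits 0 inside the window the window is truncated
  with a warning. IBS is insensitive to grid refinement (< 1e-3 between 60
  and 400 grid points, tested).

## Synthetic data

The generators define the conditions under which every statistical claim
in the test suite is measured:

* `gen_ph_weibull` — proportional hazards, Weibull(k = 1.5, λ = 1)
  baseline, standard-normal covariates (uniform and bimodal options exist
  to exercise skewed histogram shapes), inverse-CDF event times
  `T = λ(−log U · e^{−x'β})^{1/k}`, independent exponential censoring
  and/or an administrative cutoff. A helper solves the exponential rate for
  a target censoring fraction by Monte Carlo root-finding.
* `gen_competing` — simulated **directly on the subdistribution scale**:
  `F₁(t|x) = 1 − [1 − p(1 − e^{−t})]^{e^{x'β}}`, cause drawn from
  `F₁(∞|x)`, cause-1 times by inverting F₁, cause-2 times unit exponential
  conditional on cause 2 (optionally scaled by cause-2 coefficients).
  Direct simulation makes β the *exact* Fine–Gray estimand; the classic
  cause-specific-hazards construction would make it only approximate. The
  conditional cause-2 law is a modelling convenience — it does not affect
  the cause-1 estimand.
* `gen_interval` — latent proportional-hazards times observed only at
  scheduled visits (spacing δ, V visits): `(L, R]` brackets the latent
  time; events after the last visit become `(last visit, ∞)`.

Every generator is a deterministic function of its seed, and every output
passes dataset validation.

**What the simulations do not emulate:** covariate-dependent or informative
censoring, time-varying effects, non-proportional hazards, measurement
error, tied event times (times are continuous, so ties arise only in
hand-built fixtures), and the heavy-tailed or multimodal covariate joint
distributions of real cohorts. Passing tests therefore demonstrate
correctness of the estimators and pipeline under the stated models, not
robustness to their violations.

## Problem sizes

The statistical checks use: 50 datasets of n ≤ 30 for oracle agreement;
200 replicates each of n = 300 (Cox recovery and band coverage), n = 800
(Fine–Gray recovery) and n = 500 (interval Weibull recovery); 100 random
fits for the surface-contract sweep; 100 simulations for the IBS ordering
check. These sizes give Monte-Carlo standard errors of ~1.5–1.8 percentage
points on the coverage estimates, small enough to separate the nominal 95%
from a broken variance formula, while keeping the whole suite fast.

## Known limitations

* No time-varying covariates, left truncation, cure fractions, recurrent
  events, or simultaneous (uniform) confidence bands.
* Fine–Gray variance is the inverse-information approximation (above).
* Interval censoring is parametric only.
* The Cox baseline uses the Breslow formula under Efron ties (the common
  software convention), not the Efron baseline estimator.
* Missing values are handled complete-case on role columns only, with the
  dropped count logged; no imputation.
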