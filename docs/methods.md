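# Methods

## Models

The package fits two laws of leaf-level photosynthesis and one comparison
alternative.

**Exponential enzyme law.** The net photosynthetic rate responds to the
activity of a limiting enzyme as P = α·e^(b·v_p). The law follows from
assuming the relative change in P is proportional to the change in enzyme
activity while other conditions are held constant. α > 0 carries the units
of P (µmol CO₂ m⁻² s⁻¹) and is the rate at zero measured activity; b has
the reciprocal units of the activity axis and measures how strongly the
enzyme limits the rate. The model is fitted by nonlinear least squares on
the **raw rate scale**, matching how enzyme–photosynthesis series are
plotted and digitized; the assumption is additive (here: multiplicative,
small) noise around the raw curve. Note that minimizing raw-scale residuals
is not the same as regressing ln y on x; the log-linear regression is used
only as the starting point.

**Saturating nitrogen law.** On the log scale the rate follows a
Michaelis–Menten-type response to the effective nitrogen resource
s = R − R₀ ≥ 0:

    ln P = ln_P_max · s / (Kp + s) + ln_P0.

R is leaf nitrogen content (mmol m⁻² or g N m⁻², carried as metadata and
never converted), R₀ a storage-nitrogen offset, Kp the half-saturation
constant in predictor units, and ln_P0 the baseline log rate at zero
effective resource, interpreted as the contribution of stored nitrogen.
The fit minimizes residuals of **ln y** (the data are log-transformed
before this fit), assuming Gaussian noise on the log scale.

**Linear alternative.** y = intercept + slope·x by ordinary least squares
on the raw scale, the standard straight-line null against which the
exponential law is compared.

### Structural non-identifiability of the free baseline

With ln_P0 free, the nitrogen law collapses algebraically to a shifted
hyperbola

    ln P = D − B / (R − m),  D = ln_P_max + ln_P0,  B = ln_P_max·Kp,  m = R₀ − Kp.

Only (D, B, m) enter the predictions: a one-dimensional ridge of raw
parameter vectors fits any series identically, so ln_P_max, Kp, R₀ and
ln_P0 cannot be estimated jointly from a single series. The package fits
the full variant anyway (the RSS and predictions are well defined), exposes
the identifiable combinations via `hyperbola_form`, and reports the
per-parameter standard errors as undefined (singular J′J) rather than as
misleading numbers. All reference nitrogen presets therefore use the
**reduced** variant (ln_P0 ≡ 0), which is identifiable; this is also why
recovery experiments and reports parameterize the nitrogen response in
reduced form.

### Reference presets

The preset parameter sets mirror published reference fits: 13 enzyme-law
fits (α, b, their standard errors and R²) across wheat, rice, maize and
sorghum, and 7 reduced nitrogen-law fits (ln_P_max, Kp, R²) across species
at 36 and 100 Pa CO₂. The published enzyme tables label their two estimate
columns only by the variable names; the presets read them as (α, b) — the
only reading consistent with the two-parameter exponential law. The
published nitrogen tables report ln-scale maxima, so ln_P_max is stored
directly rather than P_max.

## Estimation

* **Initialization.** Exponential: OLS of ln y on x gives (e^intercept,
  slope), exact for noiseless data. Nitrogen law: a 15×15 profile grid over
  (R₀, Kp) — R₀ in [min(x) − 2·range, min(x) − ε], Kp log-spaced in
  [0.02, 20]·range — with the conditionally linear (ln_P_max, ln_P0) solved
  by linear least squares at each node; the best node seeds the optimizer.
* **Multi-start.** The deterministic start plus 8 perturbed restarts
  (multiplicative lognormal perturbations of scale parameters, shifts of
  R₀), drawn from a generator seeded by the caller, so identical inputs and
  seed reproduce results bit-for-bit. The best converged solution by RSS
  wins; converged solutions take priority over non-converged ones.
* **Constraints.** α ≥ 1e−12, Kp ≥ 1e−12, ln_P_max ≥ 1e−10 and
  R₀ ≤ min(x) − ε with ε = 1e−9 × predictor range, enforced as optimizer
  bounds (trust-region reflective), never by clipping data.
* **Convergence.** Relative RSS change < 1e−10 or gradient norm < 1e−8
  (scipy `least_squares` ftol/gtol), xtol 1e−12. If no start converges the
  result is returned flagged `converged=False`, never raised and never
  silently accepted.
* **Standard errors.** Linearized covariance s²(J′J)⁻¹ with
  s² = RSS/(n − k_model) and the analytic Jacobian at the optimum. A
  condition number above 1e12 or zero residual degrees of freedom yields
  NaN SEs with an explanatory flag instead of zeros.
* **Goodness of fit.** R² = 1 − RSS/TSS on each model's own fitting scale;
  it may be negative for misspecified fits and is not clamped; a constant
  target reports R² = 0.
* **Information criteria.** Gaussian-likelihood AIC = n·ln(RSS/n) + 2k and
  AICc = AIC + 2k(k+1)/(n−k−1), with k counting the residual variance
  (k = free curve parameters + 1) uniformly across families so AIC
  differences are comparable. AICc is reported as undefined when
  n ≤ k + 1. An RSS below 1e−20 × max(TSS, 1) is numerical noise around an
  exact fit and is treated as zero, giving the limiting AIC of −∞ so that
  exact fits tie instead of ranking floating-point dust.

## Model comparison and significance

Comparisons are restricted to families sharing a fitting scale
(exponential vs. linear on raw y; full vs. reduced nitrogen law on ln y),
because AIC values computed on different data transforms are not
comparable. Akaike weights are exp(−Δᵢ/2) normalized; the preferred model
has minimal AIC, with ties (|ΔAIC| < 1e−9, including exact fits) resolved
toward fewer parameters. The significance of a fitted relationship is
assessed by the regression F-test of the model against the intercept-only
model on its own fitting scale — a deliberate substitution for the
ANOVA/Tukey procedures sometimes quoted alongside such fits, which do not
map onto single-series regression; Tukey-style post-hoc comparisons are out
of scope. Exact fits report the limiting p = 0 with an explicit flag.

## Synthetic data

The generators emulate digitizer-style series: a deterministic design grid,
an exact model signal, and noise on the fitting scale —

* enzyme series: mean-one multiplicative lognormal noise with coefficient
  of variation `level` (default 0.05; the reference fits publish no
  residual variances, so 5% is a package default chosen as a realistic
  gas-exchange measurement error), applied to the raw-scale prediction;
* nitrogen series: additive Gaussian noise with SD `level` (default 0.05)
  on the ln scale.

Default design grids place the enzyme activity on [0.2, 2]/|b| (so the
curvature is visible within the fitted range) and leaf N on
[R₀ + 0.1·Kp, R₀ + 4·Kp] (from the rising limb to near-saturation), 12
points each for suite members. The generators are pure functions of
(parameters, design, seed); per-series seeds derive from a master seed via
`SeedSequence([master, counter])`, so extending the suite never perturbs
earlier members.

What the synthetic data do **not** emulate: pixel-quantization error from
figure digitization, between-study heterogeneity in designs and units,
non-constant noise, and correlated replicate structure. Passing recovery
tests therefore demonstrate estimator correctness under the package's
noise model, not robustness to every artefact of digitized literature data.

### Recovery experiments

`recovery_experiment` generates n_reps series, refits the generating
family, and aggregates per-parameter bias, relative bias, RMSE, median
absolute relative error, and the coverage of nominal-95% Wald intervals
built with the t quantile at the residual degrees of freedom (the
appropriate reference when s² is estimated; at n = 20 the z-based interval
is visibly anticonservative). It also records the rate at which AIC
prefers the generating family over its alternative (linear for the enzyme
law; the other baseline variant for the nitrogen law). At zero noise the
intervals have zero width, so coverage is reported NaN and flagged
degenerate. Experiment sizes used by the shipped checks — 500 replicates
at n = 20 (accuracy/coverage) and n = 30 (selection) — were chosen to make
Monte-Carlo error small relative to the quantities asserted.

## Known limitations

* ln_P0 is not estimable from one series (see above); cross-series or
  raw-scale information would be needed.
* Linearized SEs are first-order approximations; their CI coverage at 5%
  noise and n = 20 is near but not exactly nominal (~0.91–0.97 across
  parameters in the shipped experiments).
* The enzyme-law fit assumes homoscedastic raw-scale noise while the
  generator's default is (mildly heteroscedastic) multiplicative noise; at
  the 5% level the mismatch is negligible, at large noise levels it is not.
* Digitized series may contain near-duplicate x values; these are kept
  as-is, with no averaging.
* The convenience ratio ln_P_max / b mixes estimates from different
  predictor axes and is exposed for exploration only.
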