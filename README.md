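# leafedm

Enzyme-driven modelling of leaf photosynthesis in C₃ and C₄ crop plants:
fitting, simulation and model comparison for two laws that link the net
photosynthetic rate to its limiting resources.

## The scientific problem

Leaf-level photosynthesis in crops such as wheat, rice, maize and sorghum is
constrained by the activities of a handful of key enzymes (Rubisco,
cpFBPase, NADP-G3PDH, PGA kinase in the C₃ Calvin cycle; PEPC, NADP-ME, PCK
in the C₄ cycle) and, behind those, by leaf nitrogen. Two compact laws
capture this:

1. **Exponential enzyme law** — the photosynthetic rate *P*
   (µmol CO₂ m⁻² s⁻¹) rises exponentially with the activity *v_p* of a
   limiting enzyme:

   *P* = α·e^(b·v_p)

   with α the rate at zero activity (same units as *P*) and *b* the
   enzyme-activity potential (per µmol m⁻² s⁻¹).

2. **Saturating nitrogen law** — on the log scale, *P* follows a
   Michaelis–Menten-type response to the *effective* leaf nitrogen
   *R − R₀*, where *R₀* is a storage-nitrogen offset:

   ln *P* = ln *P*_max · (*R − R₀*) / (*K_p* + (*R − R₀*)) + ln *P₀*

   *K_p* is the half-saturation constant (at *R = R₀ + K_p* the log rate
   above the baseline reaches ln *P*_max / 2), and ln *P₀* is the baseline
   log rate at zero effective resource. In practice the baseline is fixed
   at zero (the "reduced" variant): with a free baseline the four
   parameters collapse to three identifiable combinations (see
   `docs/methods.md`), so ln *P₀* cannot be estimated from a single series.

The package is for plant ecophysiologists working with digitized
literature data (two-column predictor/response series) who want reproducible
nonlinear fits with standard errors, R², AIC/AICc model comparison against a
linear alternative, and parameter-recovery evidence that the estimators
behave at realistic noise levels. It ships reference parameter presets for
13 enzyme–photosynthesis fits and 7 nitrogen-response fits (species ×
CO₂ partial pressure at 36 and 100 Pa), plus a seeded synthetic-data
generator so every stage runs with no external data.

## Worked example

```python
import numpy as np
from leafedm import (ExponentialParams, NoiseSpec, compare_models,
                     fit_exponential, gen_enzyme_series, get_preset)

# simulate a wheat cpFBPase-like series at 5% noise and refit it
preset = get_preset("enzyme/Triticum_aestivum/cpFBPase")
series = gen_enzyme_series(
    preset.params,
    x_grid=np.linspace(10, 100, 20),
    noise=NoiseSpec(kind="multiplicative_lognormal", level=0.05, seed=42),
    species=preset.species,
    predictor_name=preset.enzyme,
)
fit = fit_exponential(series, seed=0)
print(f"alpha = {fit.params.alpha:.3f} (SE {fit.se[0]:.3f})")
print(f"b     = {fit.params.b:.5f} (SE {fit.se[1]:.5f})")
print(f"R^2   = {fit.r_squared:.3f}, AIC = {fit.aic:.2f}")

comparison = compare_models(series, ["exponential", "linear"], seed=0)
print(f"preferred model: {comparison.preferred} "
      f"(delta AIC = {comparison.delta_aic:.2f}, "
      f"w_exp = {comparison.akaike_weights['exponential']:.3f})")
```

prints

```
alpha = 17.285 (SE 0.601)
b     = 0.02040 (SE 0.00042)
R^2   = 0.994, AIC = 43.02
preferred model: exponential (delta AIC = 46.70, w_exp = 1.000)
```

The refit recovers the generating parameters (α = 17.37, b = 0.0203) within
their standard errors, and AIC prefers the exponential law over a straight
line by ~47 points — the data were generated from it, so they should.

The same pipeline is scriptable from the shell:

```sh
leafedm simulate --suite --seed 1 --noise 0.0 --out suite/
leafedm reproduce --registry suite/ --out reports/
leafedm compare --input suite/enzyme__Zea_mays__PCK.csv --kinds exp,linear
```

`reports/enzyme_parameters.tsv` then contains one `estimate (SE)` row per
enzyme series and `reports/nitrogen_parameters.tsv` one column per
species × CO₂ level.

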