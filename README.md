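# primecrop

Detection of **drought and temperature priming effects** on maize and
soybean yields: does a mild early-season (vegetative) drought leave a crop
better prepared for a damaging late-season (grain-filling) drought?

The package implements the full analysis chain used to answer this question
at county scale from satellite-style observations, together with a seeded
synthetic-data generator and a toy mechanistic crop simulator so the whole
chain is testable end to end without any external downloads.

## Who this is for

Agro-climatologists and crop modellers who want a reusable, tested
implementation of:

1. **Phenology detection** from 8-day two-band reflectance composites. The
   Wide Dynamic Range Vegetation Index,
   `WDRVI = (α·NIR − red)/(α·NIR + red)` with `α = 0.1`, is smoothed to a
   daily series with a GCV smoothing spline; a crop-specific reference
   seasonal curve `h(x)` is registered onto each pixel-year by bounded
   nonlinear least squares over `f(x) = yscale·h(xscale·x + tshift)`
   (shape-model fitting); the two mid-season reproductive stages are read
   off the fitted time map while emergence and maturity come from fixed
   WDRVI threshold crossings (−0.68/−0.68 maize, −0.68/−0.55 soybean).
   Pixel dates are averaged to counties, giving stage dates S1–S4 and
   durations D1–D3.
2. **Duration climate**: daily county weather (Tmax, Tmin, precipitation,
   shortwave radiation, VPD, PDSI) aggregated over the three durations, and
   standardized precipitation/temperature anomalies
   `x = (x_{y,t} − x̄_t)/δ_t` computed across years per county × duration,
   with drought-monitor-style exposure classes for PDSI, SPA, and STA.
3. **Yield anomalies** from panel models: `C1` — OLS with county fixed
   effects, common linear trend `α₀·t`, and 12 weather slopes (Tmax, Tmin,
   Srad, VPD × D1–D3; precipitation deliberately excluded so drought stays
   in the residual); `C2` — per-county linear detrending; `Ctemp` — the C1
   form with Tmax swapped out for precipitation so heat stays in the
   residual.
4. **Priming statistics**: county-years are labelled *priming* (stress in
   D1 and D3, near-normal D2), *nonpriming* (stress in D3 only), or
   *control* (no stress), compared with Welch t-tests and one-way ANOVA,
   and summarized by the mitigation arithmetic
   `mitigation_abs = mean(priming) − mean(nonpriming)`,
   `mitigation_frac = mitigation_abs / (mean(control) − mean(nonpriming))`.
5. **A mechanistic check**: a daily two-layer soil-water-balance crop
   simulator in which water stress accelerates root deepening while roots
   are still growing; the extra access to the recharged subsoil reserve is
   what lets an early-primed crop outyield an unprimed one under the same
   late drought.

## Worked example

```bash
primecrop demo --seed 7 --counties 12 --out demo/
```

runs generator → phenology → climate → anomaly (C2) → priming (PDSI) and
prints the group comparison, e.g. (seed 7, 12 counties × 19 years):

```
{
  "groups": {
    "priming":    {"n": 63, "mean": -0.015, "sd": 0.313},
    "nonpriming": {"n": 65, "mean": -0.525, "sd": 0.270},
    "control":    {"n": 98, "mean":  0.360, "sd": 0.335}
  },
  "welch_t": {"t": 9.85, "p": 3.3e-17},
  "anova":   {"F": 157.8, "p": 2.0e-43},
  "mitigation_abs_mg_ha": 0.510,
  "loss_nonpriming_mg_ha": 0.884,
  "mitigation_frac": 0.576,
  "pct_of_mean_yield": 5.0
}
```

(Means are C2 yield anomalies in Mg/Ha; values abridged to 3 digits.)
Reading: county-years that saw an early drought before their late drought
(priming) lost 0.51 Mg/Ha less than those hit cold (nonpriming) — about
58% of the drought loss was mitigated at this small problem size, against
the generator's injected mitigation fraction of 0.5 (the larger run in the
acceptance script recovers 0.46–0.50). Each stage is also available as its
own subcommand (`simulate`, `phenology`, `climate`, `anomaly`, `priming`,
`cropsim`) operating on plain CSV files, and as library functions in
`primecrop.pipeline`.

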