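# Methods

This note documents the models, the synthetic study conditions, the
numerical choices, and the known limits of what the tests demonstrate.

## The analysis chain

**WDRVI.** All phenology works on the Wide Dynamic Range Vegetation Index,
`(α·NIR − red)/(α·NIR + red)` with the NIR weighting `α = 0.1`, computed
per 8-day composite and only from composites carrying the good quality
flag. Compared with NDVI, the down-weighted NIR keeps the index responsive
at high canopy cover, which is what makes mid-season stage detection
possible at all.

**Smoothing.** Good composites are smoothed to a daily series with a cubic
smoothing spline whose penalty is chosen by generalized cross-validation,
one value per pixel-year (`scipy.interpolate.make_smoothing_spline`).
Pixel-years with fewer than 8 good composites, a span under 120 days, or a
gap over 32 days are excluded and counted in the run report rather than
imputed. Output is clipped to the index range [−1, 1].

**Shape-model registration.** A crop-specific reference curve `h(x)` with
four reference stage dates (maize 150/200/240/265; soybean
170/225/240/270, day of year) is mapped onto each pixel-year by
minimizing the RMSE of `yscale·h(xscale·x + tshift)` against the daily
series. The solver is a bounded Levenberg–Marquardt-type nonlinear least
squares (scipy's trust-region reflective `least_squares`; plain LM does
not accept the bounds). Initialization is (1, 0, 1); bounds are
`xscale ∈ [0.6, 1.6]`, `tshift ∈ [−60, 60]`, `yscale ∈ [0.3, 2.0]`, chosen
to keep the transformed season inside the calendar year and forbid
degenerate collapse. Days whose transformed argument leaves the reference
grid drop out of the loss; at least 120 days of overlap are required. A
reference date `d0` maps to the detected date `(d0 − tshift)/xscale`,
rounded half-up. The middle two stages come from this map.

**Threshold stages.** Emergence is the last upward crossing of the
emergence threshold before the fitted season peak; maturity is the first
downward crossing after it (crossings located by linear interpolation
between daily points, then rounded). Thresholds: −0.68/−0.68 for maize,
−0.68/−0.55 for soybean. The last-before/first-after tie-break is a
package choice; nothing in the method fixes which crossing to take when
the smoothed series wiggles near the threshold.

**County aggregation.** Only pixels with crop fraction ≥ 0.8 (inclusive)
enter. Stage dates are averaged over valid pixels per county-year, rounded
half-up, and durations D1–D3 recomputed from the rounded dates
(dates-first, not durations-first — the alternative ordering differs by at
most a day and is not exposed). Failed pixel-years are excluded, never
imputed.

**Validation utilities.** Weekly crop-progress area ratios are
interpolated with a two-parameter logistic `100/(1 + e^{−k(t − t50)})`;
the 50% crossing `t50` serves as the reference stage date, and agreement
is scored as RMSE in days.

**Duration climate.** Daily weather is aggregated over half-open windows
`[S_k, S_{k+1})`: means for Tmax, Tmin, radiation, VPD, and PDSI; sums for
precipitation. SPA and STA standardize the precipitation total and the
mean Tmax across years within each county × duration using the sample SD
(ddof 1) with the focal year included in its own climatology; a
leave-one-out variant is available but not default. At least 5 years are
required; a zero SD raises rather than returning ±inf. STA uses
duration-mean Tmax as its temperature variable — the same variable the
heat-variant anomaly model withholds — so heat exposure and the residual
heat signal refer to the same quantity.

**Exposure classes.** The conventional category labels leave small gaps
(e.g. between −2.0 and −1.9 on the PDSI scale); the classifiers close them
with half-open intervals cut at the round numbers, so every finite value
maps to exactly one class. A linear-scan oracle over the bin lists is kept
in the tests as an independent check.

**Anomaly models.** `C1`: OLS of yield on a common linear year trend
(year centered at the panel's first year for conditioning), county
indicator intercepts, and the 12 duration-resolved weather covariates —
precipitation excluded so drought losses stay in the residual. `Ctemp`:
same with Tmax swapped for precipitation totals, so heat effects stay in
the residual. `C2`: an independent intercept + slope per county (counties
with under 3 years are dropped and logged). Rank deficiency raises a
collinearity error naming the offending columns. No clustered or robust
standard errors are computed; the pipeline uses the fits only for
point predictions, and group inference happens downstream on the
anomalies.

**Grouping and mitigation.** Exposure windows per duration (strict
inequalities on both bounds; a value exactly on a bound matches nothing):

| index | priming (D1 / D2 / D3) | nonpriming D1 | control (all) |
|---|---|---|---|
| PDSI | <−2 / (−2,2) / <−2 | (−2,2) | (−2,2) |
| SPA | (−2,−0.5) / (−0.5,0.5) / (−2,−0.5) | (−0.5,0.5) | (−0.5,0.5) |
| STA | (0.5,2) / (−0.5,0.5) / (0.5,2) | (−0.5,0.5) | (−0.5,0.5) |

D2 and D3 windows are identical between priming and nonpriming by
construction, so the two groups differ only in early exposure. For STA the
priming D1 window demands actual early heat (lower bound +0.5); the laxer
variant with lower bound −0.5 would admit county-years with no early heat
exposure at all, contradicting the priming hypothesis being tested. For
PDSI a switch narrows the nonpriming D1 window to (0, 2). Group responses
are compared with a Welch t-test (priming vs nonpriming) and one-way
ANOVA at 0.05 without multiple-testing correction. Mitigation metrics:
absolute (priming − nonpriming mean), the fraction of the nonpriming loss
(relative to control) recovered, and the absolute value as a percent of
mean yield. Analyses for different indices run independently; a
county-year may be selected under PDSI and not under SPA.

## The synthetic generator

The generator defines the study conditions the tests and the acceptance
script run under. It emulates, statistically, what the pipeline would see
from composited satellite reflectance, gridded daily weather, and
county yield records for a rainfed Midwest-like region:

* **Canopy**: a double logistic in day of year between a bare-soil WDRVI
  of −0.78 and a peak near 0.32 (maize) / 0.25 (soybean), with its
  green-up and senescence crossings solved (fsolve) to pass exactly
  through the detection thresholds at the first and last stage dates, and
  its peak between the two middle reference dates. Every pixel-year's
  curve is the crop reference curve composed with an affine time warp, so
  stage dates, threshold crossings, and the shape-model registration are
  mutually consistent by construction. Composite noise is additive
  Gaussian in WDRVI space (default SD 0.02); flagged-bad composites
  (default rate 0.05) carry a cloud-like depressed value and must be
  dropped by the quality filter. Bands are recovered by inverting the
  WDRVI definition with a NIR profile that tracks canopy development.
* **Stage dates**: per county-year a common shift (SD 5 d) and a season
  length scale (SD 2%) applied around the calendar center, plus a small
  per-pixel shift (SD 1.5 d). The affine family keeps noise-free recovery
  exact; real scenes also deform nonlinearly, which this does not emulate.
* **Weather**: seasonal cosines for temperatures, radiation, and VPD
  (summer peak near day 199) plus iid Gaussian noise; precipitation is a
  wet-spring/drier-late-summer seasonal mean (peak day 140, default
  4 mm/day) with multiplicative lognormal noise. County offsets scale
  with the noise SDs so the zero-noise limit equals the stated
  climatology exactly.
* **Drought index**: a standardized 30-day trailing water balance
  (precipitation minus `0.12·max(Tmax − 5, 0)` demand), anomalous against
  the county's noise-free climatology, scaled by 28 mm per index unit and
  clipped to [−6, 6]. The trailing window is the memory of the index: long
  enough that a sustained precipitation deficit registers, short enough
  that an early-season drought has washed out of the index by the time
  the D2 window is evaluated — with a much longer memory no county-year
  could ever satisfy the near-normal-D2 requirement of the priming
  window, by construction of the index rather than by climate. Palmer's
  actual recursion is out of scope; only the downstream category bins
  matter.
* **Scenarios**: each county-year draws a label (control 0.4, nonpriming
  0.3, priming 0.3 by default); labels map to precipitation scaling
  windows (factor 0.15) placed inside D1 and/or D3, pulled back from the
  window ends by half the index memory so the drought does not bleed into
  D2. Realized index classification agrees with the intended label for
  at least 95% of county-years under the defaults (asserted in the
  tests; ≈98% is typical); the
  residual leakage is a real feature of classifying noisy exposure.
* **Yields**: county intercept (SD 0.6) + technology trend (0.10
  Mg/Ha/yr) + small linear sensitivities to the duration-aggregated
  weather anomalies − 1.0 Mg/Ha drought loss for late-drought labels
  + `loss × 0.5` mitigation for priming labels + Gaussian noise (SD 0.3).
  Nonpositive yields raise a configuration error instead of being
  clipped.

All draws flow from one seed through keyed substreams (weather,
reflectance, phenology, yields, scenario, crop fraction), so adding pixels
does not perturb weather draws and identical configurations are
byte-identical.

What passing tests on this generator do **not** show: robustness to mixed
pixels beyond a scalar crop fraction, to spatially correlated weather or
yield shocks, to non-affine phenological deformation, to PDSI's real
autocorrelation structure, or to reporting artifacts in survey yields.

## The crop simulator

A deliberately minimal daily model whose purpose is a mechanism
demonstration, not calibration to any cultivar.

* Demand = `kc` (0.9) × Hargreaves ET0 (temperature-based, with the
  standard extraterrestrial-radiation term at latitude 41°) × canopy cover
  (`min(1, LAI/3)` with a 0.35 bare-soil evaporative floor).
* Soil = two layers: a 0.30 m topsoil bucket fed by rain and tapped at
  22%/day of its content, and a subsoil reserve spanning the rest of the
  1.8 m potential profile, recharged to 85% at sowing, reachable at up to
  6 mm/day scaled by the rooted fraction of the subsoil. Topsoil overflow
  percolates to the subsoil; subsoil overflow drains. The daily balance
  closes to 1e-9 mm by construction and is asserted.
* Stress = unmet fraction of demand. Roots deepen at 4 mm/day times
  `1 + (boost − 1)·stress` (boost 6 by default; boost 1 switches the
  mechanism off) until 60% of the season, near flowering, after which
  depth is locked.
* Yield = potential (11 Mg/Ha) × ∏ (1 − sensitivity × mean stress) over
  season thirds with sensitivities 0.05 / 0.90 / 0.60 — reproductive
  stress is the most damaging, vegetative stress the least, which is
  precisely why a mild early drought is cheap to experience and an
  unmitigated late drought is not.
* Reported LAI is the potential bell scaled down by cumulative mean
  stress; it is a diagnostic output and does not feed back on demand
  (keeping the yield response provably monotone in late-season
  precipitation).

The priming mechanism is then emergent: an early drought stresses the
seedling while roots still grow, the boosted deepening roughly doubles
subsoil access by flowering, and under the late drought the primed crop
draws deep water that the unprimed crop cannot reach. Under the default
scenario weather the ordering control ≥ priming ≥ nonpriming holds in
100/100 paired draws with a priming benefit near +1.2 Mg/Ha, and setting
boost = 1 reverses the benefit into a pure early-drought cost — the
signal is the mechanism, not the scenario. The root-boost form is a
hypothesis embodied in a toy model; agreement with any particular
process-based simulator is not claimed, only the qualitative ordering and
the root-depth contrast.

## Problem sizes

Chosen as the package's own defaults: phenology recovery uses 20 pixels ×
5 years (noise-free and at composite noise SD 0.03 with 10% missing);
panel calibration uses 100 replicates of 50 counties × 19 years at yield
noise SD 0.2; end-to-end recovery uses 96 counties × 19 years × 2 pixels
(≈500 county-years in each of the priming and nonpriming groups after
selection); the simulator ordering uses 100 paired weather draws.

## Known limitations

* The PDSI column is a water-balance proxy sharing only the bins and the
  broad dynamics of the real index.
* SPA-based group recovery is not exercised end to end: when a sizable
  fraction of a county's years are scenario droughts, the across-year
  standardization mixes the drought and normal populations and shifts
  normal years toward the upper control bound — an inherent property of
  the anomaly definition on mixture climates, visible in the generator,
  not a code defect.
* Group comparisons ignore spatial and serial correlation between
  county-years, as does the panel fit.
* The simulator has no nitrogen, pests, phenology feedback, or canopy
  water-demand feedback; its numbers are not yields of any real system.
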