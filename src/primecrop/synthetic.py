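"""Seeded synthetic counties, pixels, weather, and yields with known truth.

The generator emulates the statistical structure of the real inputs the
pipeline is designed for — 8-day two-band reflectance composites, daily
county weather with a wetter-spring / drier-summer seasonal cycle, and
county-year yields with technology trend, county intercepts, weather
sensitivities, a late-season drought loss, and a priming mitigation term —
while recording the ground truth (stage dates, scenario labels, injected
yield components) that makes every downstream stage testable.

Canopy seasonality is a double-logistic WDRVI curve whose green-up and
senescence crossings hit the emergence/maturity detection thresholds exactly
at the true first and last stage dates; each pixel-year's curve is an affine
time warp of the crop's reference curve, so the shape-model fit can recover
the middle stage dates exactly in the noise-free limit. The drought index
column is a standardized running water balance (precipitation minus a
temperature-scaled demand) rather than Palmer's recursion: only the
classification bins matter downstream.

All randomness flows from one seed through keyed substreams
(weather/reflectance/phenology/yields/scenario), so adding pixels does not
perturb weather draws and identical configurations are byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import fsolve

from .errors import ConfigError, InputError
from . import climate as climate_mod
from . import phenology as phen_mod

GROUPS = ("control", "nonpriming", "priming", "other")

# substream keys (mixed into the rng seed sequence)
_S_WEATHER, _S_REFL, _S_PHENO, _S_YIELD, _S_SCENARIO, _S_CDL = range(6)

#: Canopy-curve constants per crop: WDRVI floor/ceiling and the green-up /
#: senescence logistic widths (days). Widths are chosen so the curve peak
#: falls between the 2nd and 3rd reference stage dates.
CANOPY_CONSTANTS = {
    "maize": {"vmin": -0.78, "vmax": 0.35, "width_up": 9.0, "width_down": 8.0},
    "soybean": {"vmin": -0.78, "vmax": 0.30, "width_up": 12.0, "width_down": 7.0},
}

_DEFAULT_CLIMATOLOGY = {
    # deg C; seasonal cosine peaking at DOY 199
    "tmax": {"mean": 16.0, "amp": 16.5, "sd": 2.5},
    "tmin": {"mean": 4.5, "amp": 13.5, "sd": 2.0},
    # mm/day; wet spring (peak DOY 140), drier late summer
    "precip": {"mean": 4.0, "amp": 0.35, "sd": 0.5},
    # W/m2
    "srad": {"mean": 180.0, "amp": 95.0, "sd": 15.0},
    # kPa
    "vpd": {"mean": 0.75, "amp": 0.55, "sd": 0.12},
}

_DEFAULT_SENSITIVITIES = {
    # Mg/Ha per unit of the duration aggregate (deg C, W/m2, kPa)
    "tmax": (-0.03, -0.08, -0.05),
    "tmin": (0.015, 0.0, 0.0),
    "srad": (0.003, 0.005, 0.003),
    "vpd": (-0.15, -0.40, -0.25),
}

_DEFAULT_PROPORTIONS = {
    "control": 0.4, "nonpriming": 0.3, "priming": 0.3, "other": 0.0,
}

_TEMP_PEAK_DOY = 199
_PRECIP_PEAK_DOY = 140


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic scenario."""

    seed: int = 0
    n_counties: int = 12
    years: tuple = tuple(range(2000, 2019))
    pixels_per_county: int = 3
    crop: str = "maize"
    stage_date_means: tuple = (150.0, 200.0, 240.0, 265.0)
    stage_date_sd: float = 5.0  # common shift of all four dates, days
    stage_scale_sd: float = 0.02  # season length scale jitter
    pixel_shift_sd: float = 1.5  # within-county pixel date jitter, days
    composite_noise_sd: float = 0.02  # WDRVI units
    missing_rate: float = 0.05
    weather_climatology: dict = field(
        default_factory=lambda: {k: dict(v) for k, v in _DEFAULT_CLIMATOLOGY.items()}
    )
    county_offset_frac: float = 0.4  # county systematic offset, x variable sd
    trend_slope: float = 0.10  # Mg/Ha per year
    county_intercept_sd: float = 0.6  # Mg/Ha
    base_yield: float = 9.8  # Mg/Ha (maize-scale)
    weather_sensitivities: dict = field(
        default_factory=lambda: {k: tuple(v) for k, v in _DEFAULT_SENSITIVITIES.items()}
    )
    drought_loss: float = 1.0  # Mg/Ha
    priming_mitigation_frac: float = 0.5
    yield_noise_sd: float = 0.3  # Mg/Ha
    group_proportions: dict = field(
        default_factory=lambda: dict(_DEFAULT_PROPORTIONS)
    )
    # drought-index proxy: standardized running water balance
    pdsi_window_days: int = 30
    pdsi_scale_mm: float = 28.0
    drought_precip_scale: float = 0.15  # precip multiplier inside drought windows
    low_fraction_rate: float = 0.15  # share of pixel-years below the CDL cutoff

    def __post_init__(self):
        self.years = tuple(int(y) for y in self.years)
        self.stage_date_means = tuple(float(v) for v in self.stage_date_means)
        if self.crop not in CANOPY_CONSTANTS:
            raise ConfigError(f"unknown crop {self.crop!r}")
        for name in ("stage_date_sd", "stage_scale_sd", "pixel_shift_sd",
                     "composite_noise_sd", "county_intercept_sd",
                     "yield_noise_sd", "drought_loss"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be nonnegative")
        if not 0 <= self.missing_rate < 1:
            raise ConfigError("missing_rate must lie in [0, 1)")
        if not 0 <= self.priming_mitigation_frac <= 1:
            raise ConfigError("priming_mitigation_frac must lie in [0, 1]")
        if any(b <= a for a, b in zip(self.stage_date_means,
                                      self.stage_date_means[1:])):
            raise ConfigError("stage_date_means must be strictly increasing")
        p = self.group_proportions
        if any(v < 0 for v in p.values()) or not np.isclose(sum(p.values()), 1.0):
            raise ConfigError("group_proportions must be nonnegative and sum to 1")
        for var, spec in self.weather_climatology.items():
            if spec.get("sd", 0.0) < 0:
                raise ConfigError(f"{var} climatology sd must be nonnegative")


@dataclass
class SyntheticTruth:
    """Ground truth recorded while generating a scenario."""

    pixel_stages: pd.DataFrame  # county_id, pixel_id, year, s1..s4 (float)
    county_stages: pd.DataFrame  # county_id, year, s1..s4 (float means)
    labels: pd.DataFrame  # county_id, year, label
    components: pd.DataFrame  # injected yield components per county-year

    def to_json(self, path):
        payload = {
            "pixel_stages": self.pixel_stages.to_dict(orient="list"),
            "county_stages": self.county_stages.to_dict(orient="list"),
            "labels": self.labels.to_dict(orient="list"),
            "components": self.components.to_dict(orient="list"),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path):
        with open(path) as fh:
            payload = json.load(fh)
        return cls(**{k: pd.DataFrame(v) for k, v in payload.items()})


@dataclass
class ScenarioBundle:
    """All tables for one synthetic scenario, keyed consistently."""

    reflectance: pd.DataFrame
    weather: pd.DataFrame
    yields: pd.DataFrame
    cdl: pd.DataFrame
    cpr: pd.DataFrame
    truth: SyntheticTruth
    config: SimulationConfig

    def write(self, outdir):
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.reflectance.to_csv(outdir / "reflectance.csv", index=False)
        self.weather.to_csv(outdir / "weather.csv", index=False)
        self.yields.to_csv(outdir / "yields.csv", index=False)
        self.cdl.to_csv(outdir / "cdl.csv", index=False)
        self.cpr.to_csv(outdir / "cpr.csv", index=False)
        self.truth.to_json(outdir / "truth.json")
        return outdir


# --------------------------------------------------------------------------
# canopy reference curve

class CanopyCurve:
    """Double-logistic WDRVI seasonality anchored at emergence/maturity.

    The green-up inflection and senescence crossing are solved so the curve
    passes exactly through the crop's detection thresholds at the first and
    last reference stage dates.
    """

    def __init__(self, crop, stage_dates=None):
        consts = CANOPY_CONSTANTS[crop]
        phen = phen_mod.CROP_CONSTANTS[crop]
        dates = tuple(stage_dates) if stage_dates is not None \
            else tuple(float(d) for d in phen["reference_dates"])
        if any(b <= a for a, b in zip(dates, dates[1:])):
            raise InputError("stage dates must be strictly increasing")
        self.crop = crop
        self.stage_dates = dates
        self.vmin = consts["vmin"]
        self.vmax = consts["vmax"]
        self.bu = consts["width_up"]
        self.bd = consts["width_down"]
        up, dn = phen["up_threshold"], phen["down_threshold"]
        delta = self.vmax - self.vmin

        def _sig(z):
            return 1.0 / (1.0 + np.exp(-z))

        def _eqs(p):
            a, c = p
            f = lambda d: self.vmin + delta * (_sig((d - a) / self.bu)
                                               - _sig((d - c) / self.bd))
            return [f(dates[0]) - up, f(dates[3]) - dn]

        a0 = dates[0] + 2.3 * self.bu
        c0 = dates[3] - 2.3 * self.bd
        (self.a, self.c), info, ier, _ = fsolve(_eqs, [a0, c0], full_output=True)
        if ier != 1:  # pragma: no cover - well-posed for sane presets
            raise ConfigError("canopy curve anchoring did not converge")

    def __call__(self, doy):
        doy = np.asarray(doy, dtype=float)
        delta = self.vmax - self.vmin
        return self.vmin + delta * (
            1.0 / (1.0 + np.exp(-(doy - self.a) / self.bu))
            - 1.0 / (1.0 + np.exp(-(doy - self.c) / self.bd))
        )


def _affine_from_dates(reference_dates, stage_dates):
    """Least-squares affine map w(m) = shift + scale*m from reference to
    pixel stage dates (exact when the dates are an affine warp)."""
    m = np.asarray(reference_dates, dtype=float)
    s = np.asarray(stage_dates, dtype=float)
    A = np.column_stack([np.ones_like(m), m])
    (shift, scale), *_ = np.linalg.lstsq(A, s, rcond=None)
    if scale <= 0:
        raise InputError("degenerate stage-date warp (nonpositive time scale)")
    return shift, scale


def pixel_canopy_curve(true_stage_dates, crop):
    """Daily WDRVI function for a pixel-year: the crop reference curve
    composed with the affine time warp implied by the true stage dates."""
    ref = CanopyCurve(crop)
    shift, scale = _affine_from_dates(ref.stage_dates, true_stage_dates)

    def curve(doy):
        return ref((np.asarray(doy, dtype=float) - shift) / scale)

    return curve


def reference_shape_model(config, grid=None):
    """Shape model built from the crop's noise-free reference canopy curve,
    with the configured mean stage dates as the reference dates (the
    synthetic analogue of calibrating the model at well-observed sites)."""
    curve = pixel_canopy_curve(config.stage_date_means, config.crop)
    if grid is None:
        grid = np.arange(1.0, 366.0)
    return phen_mod.ShapeModel(crop=config.crop, grid=np.asarray(grid, float),
                               curve=curve(grid),
                               reference_dates=config.stage_date_means)


# --------------------------------------------------------------------------
# weather

def _seasonal(spec, doy, peak_doy):
    return spec["mean"] + spec.get("amp", 0.0) * np.cos(
        2.0 * np.pi * (doy - peak_doy) / 365.25
    )


def _county_offsets(config, county):
    """Systematic per-county climate offsets (scale with the noise SDs)."""
    rng = np.random.default_rng([config.seed, _S_WEATHER, int(county)])
    z = rng.standard_normal(len(config.weather_climatology))
    out = {}
    for zi, (var, spec) in zip(z, config.weather_climatology.items()):
        out[var] = config.county_offset_frac * spec.get("sd", 0.0) * zi
    return out


def _daily_fields(config, county, year, precip_scales, with_noise):
    doy = np.arange(1, 366)
    clim = config.weather_climatology
    offs = _county_offsets(config, county)
    rng = np.random.default_rng([config.seed, _S_WEATHER, int(county), int(year)])

    tmax = _seasonal(clim["tmax"], doy, _TEMP_PEAK_DOY) + offs["tmax"]
    tmin = _seasonal(clim["tmin"], doy, _TEMP_PEAK_DOY) + offs["tmin"]
    srad = _seasonal(clim["srad"], doy, _TEMP_PEAK_DOY) + offs["srad"]
    vpd = _seasonal(clim["vpd"], doy, _TEMP_PEAK_DOY) + offs["vpd"]
    precip_mean = np.maximum(
        _seasonal(
            {"mean": clim["precip"]["mean"],
             "amp": clim["precip"].get("amp", 0.0) * clim["precip"]["mean"]},
            doy, _PRECIP_PEAK_DOY,
        ) + offs["precip"],
        0.0,
    )
    if with_noise:
        tmax = tmax + rng.normal(0.0, clim["tmax"]["sd"], doy.size)
        tmin = tmin + rng.normal(0.0, clim["tmin"]["sd"], doy.size)
        srad = srad + rng.normal(0.0, clim["srad"]["sd"], doy.size)
        vpd = vpd + rng.normal(0.0, clim["vpd"]["sd"], doy.size)
        sig = clim["precip"]["sd"]
        if sig > 0:
            precip = precip_mean * rng.lognormal(-0.5 * sig**2, sig, doy.size)
        else:
            precip = precip_mean.copy()
    else:
        precip = precip_mean.copy()
    for lo, hi, scale in precip_scales or ():
        mask = (doy >= lo) & (doy <= hi)
        precip = np.where(mask, precip * scale, precip)
    tmin = np.minimum(tmin, tmax - 0.2)
    return {
        "doy": doy,
        "tmax": tmax,
        "tmin": tmin,
        "precip": np.maximum(precip, 0.0),
        "srad": np.maximum(srad, 0.0),
        "vpd": np.maximum(vpd, 0.0),
    }


def _water_balance(precip, tmax, window):
    """Trailing-window sum of (precip - temperature-scaled demand)."""
    demand = 0.12 * np.maximum(tmax - 5.0, 0.0)
    net = precip - demand
    # pad with the first value so early-season windows are well defined
    padded = np.concatenate([np.full(window - 1, net[:7].mean()), net])
    kernel = np.ones(window)
    return np.convolve(padded, kernel, mode="valid")


def simulate_weather(config, county, year, precip_scales=None):
    """Daily weather table for one county-year.

    ``precip_scales`` is an optional list of ``(start_doy, end_doy, scale)``
    windows multiplying precipitation — the scenario switch that forces
    drought inside chosen phenological durations. The drought-index column
    is the standardized trailing water balance (precipitation minus
    temperature-scaled demand over ``config.pdsi_window_days``), anomalous
    relative to the county's noise-free climatology and clipped to [-6, 6].
    """
    if int(year) not in config.years:
        raise InputError(f"year {year} not in configured years")
    if not 0 <= int(county) < config.n_counties:
        raise InputError(f"county {county} outside 0..{config.n_counties - 1}")
    f = _daily_fields(config, county, year, precip_scales, with_noise=True)
    ref = _daily_fields(config, county, year, None, with_noise=False)
    wb = _water_balance(f["precip"], f["tmax"], config.pdsi_window_days)
    wb_ref = _water_balance(ref["precip"], ref["tmax"], config.pdsi_window_days)
    pdsi = np.clip((wb - wb_ref) / config.pdsi_scale_mm, -6.0, 6.0)
    dates = pd.Timestamp(f"{year}-01-01") + pd.to_timedelta(f["doy"] - 1, unit="D")
    return pd.DataFrame({
        "county_id": int(county),
        "date": dates.strftime("%Y-%m-%d"),
        "year": int(year),
        "doy": f["doy"],
        "tmax_c": f["tmax"],
        "tmin_c": f["tmin"],
        "precip_mm": f["precip"],
        "srad_wm2": f["srad"],
        "vpd_kpa": f["vpd"],
        "pdsi": pdsi,
    })


def drought_windows(config, label):
    """Scenario precipitation-scaling windows for a truth label."""
    m = config.stage_date_means
    s = config.drought_precip_scale
    half = config.pdsi_window_days / 2.0
    # Window ends are pulled back from the next stage boundary so the
    # trailing water-balance window does not drag the drought into D2.
    early = (m[0] - 10.0, m[1] - half, s)  # depresses the index across D1
    late = (max(m[1] + 5.0, m[2] - half), m[3], s)  # across D3
    return {
        "control": (),
        "nonpriming": (late,),
        "priming": (early, late),
        "other": (early,),
    }[label]


def scenario_weather_sets(config, n_per_scenario,
                          scenarios=("control", "nonpriming", "priming")):
    """Paired weather realizations per scenario for simulator experiments.

    Each realization i uses one (county, year) weather draw; the scenarios
    differ only in their drought-window precipitation scaling, so
    comparisons across scenarios are paired.
    """
    pairs = [(c, y) for c in range(config.n_counties) for y in config.years]
    if n_per_scenario > len(pairs):
        raise InputError(
            f"{n_per_scenario} realizations requested but only {len(pairs)} "
            "county-year draws available in the configuration"
        )
    out = {name: [] for name in scenarios}
    for county, year in pairs[:n_per_scenario]:
        for name in scenarios:
            out[name].append(
                simulate_weather(config, county, year,
                                 precip_scales=drought_windows(config, name))
            )
    return out


# --------------------------------------------------------------------------
# reflectance

def _invert_wdrvi(v, alpha=phen_mod.DEFAULT_ALPHA):
    """Two-band reflectances whose WDRVI equals ``v`` exactly.

    The NIR band tracks canopy development linearly; the red band is solved
    from the WDRVI definition.
    """
    v = np.asarray(v, dtype=float)
    b2 = 0.18 + 0.32 * np.clip((v + 0.78) / 1.13, 0.0, 1.0)
    b1 = alpha * b2 * (1.0 - v) / (1.0 + v)
    return b1, b2


def simulate_reflectance(true_stage_dates, config, rng=None):
    """8-day two-band composites for one pixel-year.

    The exact WDRVI of the emitted bands equals the pixel's double-logistic
    canopy curve at the composite DOYs plus additive Gaussian noise; a
    fraction ``missing_rate`` of composites is flagged bad (bad composites
    carry a cloud-like depressed value and are meant to be dropped).
    """
    if rng is None:
        rng = np.random.default_rng([config.seed, _S_REFL])
    curve = pixel_canopy_curve(true_stage_dates, config.crop)
    doys = np.arange(1, 366, 8)
    v = curve(doys.astype(float))
    v = v + rng.normal(0.0, config.composite_noise_sd, doys.size)
    bad = rng.random(doys.size) < config.missing_rate
    v = np.where(bad, v - np.abs(rng.normal(0.3, 0.1, doys.size)), v)
    v = np.clip(v, -0.97, 0.97)
    b1, b2 = _invert_wdrvi(v)
    return pd.DataFrame({
        "doy": doys,
        "ref_b1": b1,
        "ref_b2": b2,
        "qc_flag": np.where(bad, "bad", "good"),
    })


# --------------------------------------------------------------------------
# yields

def _climatological_duration_reference(config):
    """Noise-free duration aggregates at the mean stage dates (the centering
    point for the weather sensitivity terms)."""
    f = _daily_fields(config, 0, config.years[0], None, with_noise=False)
    # strip county offsets by rebuilding without them
    doy = f["doy"]
    clim = config.weather_climatology
    fields = {
        "tmax": _seasonal(clim["tmax"], doy, _TEMP_PEAK_DOY),
        "tmin": _seasonal(clim["tmin"], doy, _TEMP_PEAK_DOY),
        "srad": _seasonal(clim["srad"], doy, _TEMP_PEAK_DOY),
        "vpd": _seasonal(clim["vpd"], doy, _TEMP_PEAK_DOY),
    }
    m = [int(round(v)) for v in config.stage_date_means]
    ref = {}
    for j, (lo, hi) in enumerate(zip(m[:-1], m[1:])):
        win = (doy >= lo) & (doy < hi)
        for var, arr in fields.items():
            ref[(var, j)] = float(arr[win].mean())
    return ref


def simulate_yields(config, duration_climate, truth_labels,
                    return_components=False):
    """County-year yields from duration climate and scenario labels.

    yield = base + county intercept + trend*(year - y0)
            + sum_j sens_var_j * (aggregate - climatological reference)
            - drought_loss * 1[late drought]
            + drought_loss * priming_mitigation_frac * 1[label == priming]
            + noise.

    Late drought applies to the ``priming`` and ``nonpriming`` labels; the
    mitigation term only to ``priming``. Raises ``ConfigError`` if any
    resulting yield is nonpositive (effect sizes too large).
    """
    ref = _climatological_duration_reference(config)
    y0 = min(config.years)
    wide = duration_climate.pivot_table(
        index=["county_id", "year"], columns="duration",
        values=["tmax", "tmin", "srad", "vpd"],
    )
    labels = truth_labels.set_index(["county_id", "year"])["label"]
    rows = []
    for (county, year), row in wide.iterrows():
        if (county, year) not in labels.index:
            raise InputError(f"no truth label for county {county} year {year}")
        label = labels.loc[(county, year)]
        rng_c = np.random.default_rng([config.seed, _S_YIELD, int(county)])
        intercept = config.base_yield + rng_c.normal(0.0, config.county_intercept_sd)
        trend = config.trend_slope * (year - y0)
        weather = 0.0
        for var, coefs in config.weather_sensitivities.items():
            for j, dur in enumerate(climate_mod.DURATIONS):
                weather += coefs[j] * (row[(var, dur)] - ref[(var, j)])
        loss = config.drought_loss if label in ("priming", "nonpriming") else 0.0
        mitigation = (config.drought_loss * config.priming_mitigation_frac
                      if label == "priming" else 0.0)
        rng_y = np.random.default_rng([config.seed, _S_YIELD, int(county), int(year)])
        noise = rng_y.normal(0.0, config.yield_noise_sd)
        total = intercept + trend + weather - loss + mitigation + noise
        if total <= 0:
            raise ConfigError(
                f"nonpositive yield ({total:.2f} Mg/Ha) for county {county} "
                f"year {year}: effect sizes too large for the base yield"
            )
        rows.append({
            "county_id": county, "year": year, "crop": config.crop,
            "yield_mg_ha": total, "intercept": intercept, "trend": trend,
            "weather": weather, "drought_loss": loss, "mitigation": mitigation,
            "noise": noise,
        })
    out = pd.DataFrame(rows)
    yields = out[["county_id", "year", "crop", "yield_mg_ha"]]
    if return_components:
        return yields, out.drop(columns=["crop", "yield_mg_ha"])
    return yields


# --------------------------------------------------------------------------
# scenario assembly

def _draw_stage_dates(config, county, year):
    rng = np.random.default_rng([config.seed, _S_PHENO, int(county), int(year)])
    m = np.asarray(config.stage_date_means)
    center = m.mean()
    shift = rng.normal(0.0, config.stage_date_sd)
    scale = max(rng.normal(1.0, config.stage_scale_sd), 0.7)
    county_dates = center + scale * (m - center) + shift
    pixel_dates = []
    for p in range(config.pixels_per_county):
        ps = rng.normal(0.0, config.pixel_shift_sd)
        pixel_dates.append(county_dates + ps)
    return county_dates, pixel_dates


def _cpr_table(config, county_stages):
    """Weekly crop-progress area ratios per stage from statewide mean dates."""
    rows = []
    stage_cols = ["s1", "s2", "s3", "s4"]
    for year, grp in county_stages.groupby("year"):
        for k, col in enumerate(stage_cols):
            mu = grp[col].mean()
            weeks = np.arange(int(mu) - 28, int(mu) + 29, 7)
            ratio = 100.0 / (1.0 + np.exp(-(weeks - mu) / 3.5))
            for w, r in zip(weeks, ratio):
                rows.append({
                    "state_id": 0, "year": int(year), "stage": k + 1,
                    "week_doy": int(w), "area_ratio": float(r),
                })
    return pd.DataFrame(rows)


def make_scenario(config):
    """Generate a full synthetic dataset bundle plus ground truth.

    Scenario labels (control / nonpriming / priming / other) are drawn per
    county-year with the configured proportions; each label maps to
    precipitation-scaling windows that force drought in the corresponding
    durations. Yields embed the generative structure the anomaly and
    priming stages assume.
    """
    label_rows, pix_rows, cty_rows = [], [], []
    weather_parts, refl_parts, cdl_rows = [], [], []
    group_names = list(config.group_proportions)
    probs = np.array([config.group_proportions[g] for g in group_names])
    for county in range(config.n_counties):
        for year in config.years:
            rng_s = np.random.default_rng(
                [config.seed, _S_SCENARIO, county, int(year)]
            )
            label = group_names[rng_s.choice(len(group_names), p=probs)]
            label_rows.append({"county_id": county, "year": int(year),
                               "label": label})
            weather_parts.append(
                simulate_weather(config, county, year,
                                 precip_scales=drought_windows(config, label))
            )
            county_dates, pixel_dates = _draw_stage_dates(config, county, year)
            cty_rows.append({
                "county_id": county, "year": int(year),
                **{f"s{k + 1}": float(d) for k, d in enumerate(county_dates)},
            })
            for p, dates in enumerate(pixel_dates):
                pixel_id = county * config.pixels_per_county + p
                pix_rows.append({
                    "county_id": county, "pixel_id": pixel_id,
                    "year": int(year),
                    **{f"s{k + 1}": float(d) for k, d in enumerate(dates)},
                })
                rng_r = np.random.default_rng(
                    [config.seed, _S_REFL, county, pixel_id, int(year)]
                )
                refl = simulate_reflectance(dates, config, rng=rng_r)
                refl.insert(0, "year", int(year))
                refl.insert(0, "county_id", county)
                refl.insert(0, "pixel_id", pixel_id)
                refl_parts.append(refl)
                rng_f = np.random.default_rng(
                    [config.seed, _S_CDL, county, pixel_id, int(year)]
                )
                if rng_f.random() < config.low_fraction_rate:
                    frac = rng_f.uniform(0.30, 0.75)
                else:
                    frac = rng_f.uniform(0.82, 0.98)
                cdl_rows.append({"pixel_id": pixel_id, "year": int(year),
                                 "crop_fraction": frac})

    labels = pd.DataFrame(label_rows)
    county_stages = pd.DataFrame(cty_rows)
    pixel_stages = pd.DataFrame(pix_rows)
    weather = pd.concat(weather_parts, ignore_index=True)

    # duration climate at the TRUE county stage dates feeds yield generation
    records = []
    for row in county_stages.itertuples(index=False):
        stages = tuple(int(np.floor(v + 0.5)) for v in (row.s1, row.s2, row.s3, row.s4))
        records.append(phen_mod.PhenologyRecord(
            county_id=row.county_id, year=row.year, crop=config.crop,
            stages=stages, n_pixels=config.pixels_per_county,
        ))
    true_climate = climate_mod.build_duration_climate(weather, records)
    yields, components = simulate_yields(config, true_climate, labels,
                                         return_components=True)
    truth = SyntheticTruth(pixel_stages=pixel_stages,
                           county_stages=county_stages, labels=labels,
                           components=components)
    return ScenarioBundle(
        reflectance=pd.concat(refl_parts, ignore_index=True),
        weather=weather, yields=yields, cdl=pd.DataFrame(cdl_rows),
        cpr=_cpr_table(config, county_stages), truth=truth, config=config,
    )
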