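"""Crop phenological stage detection from two-band reflectance composites.

The detection pipeline follows the hybrid strategy used for MODIS-scale crop
phenology mapping: per-pixel WDRVI time series are spline-smoothed to a daily
grid, a crop-specific reference seasonal curve (the "shape model") is
registered onto each pixel-year by a three-parameter geometric transformation

    f(x) = yscale * h(xscale * x + tshift),

and the two mid-season reproductive stages are read off the fitted time
mapping, while emergence and maturity come from fixed WDRVI threshold
crossings on the smoothed series. Pixel-level stage dates are averaged to the
county level and validated against 50%-crossing dates interpolated from
weekly crop-progress area ratios.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import make_smoothing_spline
from scipy.optimize import curve_fit, least_squares

from .errors import DetectionError, InputError, QualityError

logger = logging.getLogger(__name__)

#: WDRVI weighting coefficient (NIR down-weighting).
DEFAULT_ALPHA = 0.1

#: Per-crop detection constants: reference stage dates (day of year) for the
#: four stages, and the WDRVI thresholds used for emergence (upward crossing)
#: and maturity (downward crossing).
CROP_CONSTANTS = {
    "maize": {
        "reference_dates": (150, 200, 240, 265),
        "up_threshold": -0.68,
        "down_threshold": -0.68,
        "stage_names": ("emergence", "silking", "dent", "maturity"),
    },
    "soybean": {
        "reference_dates": (170, 225, 240, 270),
        "up_threshold": -0.68,
        "down_threshold": -0.55,
        "stage_names": (
            "emergence",
            "beginning_seed",
            "full_seed",
            "beginning_maturity",
        ),
    },
}

#: Stages detected through the shape-model fit (the middle two); emergence
#: and the final maturity stage come from the threshold method.
SMF_STAGES = (1, 2)

#: Default crop-fraction cutoff for retaining pixels (inclusive).
MIN_CROP_FRACTION = 0.8

#: Quality screening: minimum number of good composites, minimum span in
#: days, and the longest tolerated gap between good composites.
MIN_COMPOSITES = 8
MIN_SPAN_DAYS = 120
MAX_GAP_DAYS = 32

#: Shape-model fit bounds ((xscale, tshift, yscale) lower/upper) and start.
FIT_BOUNDS = ([0.6, -60.0, 0.3], [1.6, 60.0, 2.0])
FIT_INIT = (1.0, 0.0, 1.0)


def _round_half_up(x):
    return np.floor(np.asarray(x, dtype=float) + 0.5).astype(int)


@dataclass(frozen=True)
class ShapeModel:
    """Crop-specific daily reference WDRVI curve with four reference dates."""

    crop: str
    grid: np.ndarray  # daily DOY grid
    curve: np.ndarray  # reference WDRVI h(x) on the grid
    reference_dates: tuple  # four strictly increasing DOYs

    def __post_init__(self):
        grid = np.asarray(self.grid, dtype=float)
        curve = np.asarray(self.curve, dtype=float)
        if grid.shape != curve.shape:
            raise InputError("shape model grid and curve lengths differ")
        refs = tuple(float(d) for d in self.reference_dates)
        if len(refs) != 4 or any(b <= a for a, b in zip(refs, refs[1:])):
            raise InputError("reference dates must be 4 strictly increasing DOYs")
        if refs[0] < grid[0] or refs[-1] > grid[-1]:
            raise InputError("reference dates outside the model grid")
        peak = grid[int(np.argmax(curve))]
        if not (refs[1] < peak < refs[2]):
            raise InputError(
                f"model peak at DOY {peak:.1f} not between reference dates "
                f"{refs[1]:.0f} and {refs[2]:.0f}"
            )
        object.__setattr__(self, "grid", grid)
        object.__setattr__(self, "curve", curve)
        object.__setattr__(self, "reference_dates", refs)

    @property
    def peak_doy(self) -> float:
        return float(self.grid[int(np.argmax(self.curve))])

    def __call__(self, x):
        """Evaluate h by linear interpolation; NaN outside the grid."""
        x = np.asarray(x, dtype=float)
        out = np.interp(x, self.grid, self.curve)
        out = np.where((x < self.grid[0]) | (x > self.grid[-1]), np.nan, out)
        return out

    def to_json(self, path):
        payload = {
            "crop": self.crop,
            "grid": self.grid.tolist(),
            "curve": self.curve.tolist(),
            "reference_dates": list(self.reference_dates),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path):
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            crop=payload["crop"],
            grid=np.asarray(payload["grid"], dtype=float),
            curve=np.asarray(payload["curve"], dtype=float),
            reference_dates=tuple(payload["reference_dates"]),
        )


@dataclass
class WdrviSeries:
    """Daily smoothed WDRVI series for one pixel-year."""

    pixel_id: object
    year: int
    grid: np.ndarray
    values: np.ndarray
    alpha: float = DEFAULT_ALPHA

    def __call__(self, x):
        x = np.asarray(x, dtype=float)
        out = np.interp(x, self.grid, self.values)
        return np.where((x < self.grid[0]) | (x > self.grid[-1]), np.nan, out)


@dataclass
class SmfFit:
    """Result of registering the shape model onto one pixel-year."""

    xscale: float
    tshift: float
    yscale: float
    rmse: float
    converged: bool
    iterations: int


@dataclass
class PhenologyRecord:
    """County-year stage dates and the three inter-stage durations."""

    county_id: object
    year: int
    crop: str
    stages: tuple  # S1..S4, integer DOY
    n_pixels: int
    durations: tuple = field(init=False)

    def __post_init__(self):
        s = tuple(int(v) for v in self.stages)
        if len(s) != 4 or any(b <= a for a, b in zip(s, s[1:])):
            raise DetectionError(
                f"county {self.county_id} year {self.year}: stage dates "
                f"{s} are not strictly increasing"
            )
        self.stages = s
        self.durations = (s[1] - s[0], s[2] - s[1], s[3] - s[2])


def compute_wdrvi(doys, ref_b1, ref_b2, qc_flag=None, alpha=DEFAULT_ALPHA):
    """Wide Dynamic Range Vegetation Index for the good composites.

    WDRVI = (alpha * NIR - red) / (alpha * NIR + red), with the NIR band
    down-weighted by ``alpha`` (default 0.1) to linearize the response at
    high canopy cover. Composites flagged bad are dropped.

    Returns ``(doys, wdrvi)`` arrays restricted to good composites.
    """
    if alpha <= 0:
        raise InputError("alpha must be positive")
    doys = np.asarray(doys, dtype=float)
    b1 = np.asarray(ref_b1, dtype=float)
    b2 = np.asarray(ref_b2, dtype=float)
    if qc_flag is None:
        good = np.ones(doys.shape, dtype=bool)
    else:
        qc = np.asarray(qc_flag)
        good = (qc == "good") | (qc == 0) | (qc == True)  # noqa: E712
    if not good.any():
        raise QualityError("all composites flagged bad")
    doys, b1, b2 = doys[good], b1[good], b2[good]
    denom = alpha * b2 + b1
    if np.any(denom == 0):
        raise InputError("zero WDRVI denominator (alpha*b2 + b1 == 0)")
    return doys, (alpha * b2 - b1) / denom


def smooth_daily(doys, wdrvi, pixel_id=None, year=None, alpha=DEFAULT_ALPHA):
    """Smooth composite WDRVI to a daily series with a GCV smoothing spline.

    Requires at least ``MIN_COMPOSITES`` good composites spanning at least
    ``MIN_SPAN_DAYS`` days with no gap longer than ``MAX_GAP_DAYS``; the
    smoothing parameter is chosen by generalized cross-validation per
    pixel-year. Output is clipped to the WDRVI range [-1, 1].
    """
    doys = np.asarray(doys, dtype=float)
    wdrvi = np.asarray(wdrvi, dtype=float)
    order = np.argsort(doys)
    doys, wdrvi = doys[order], wdrvi[order]
    if len(doys) < MIN_COMPOSITES:
        raise QualityError(
            f"only {len(doys)} good composites (< {MIN_COMPOSITES})"
        )
    span = doys[-1] - doys[0]
    if span < MIN_SPAN_DAYS:
        raise QualityError(f"composite span {span:.0f} d < {MIN_SPAN_DAYS} d")
    gaps = np.diff(doys)
    if gaps.max() > MAX_GAP_DAYS:
        raise QualityError(f"gap of {gaps.max():.0f} d exceeds {MAX_GAP_DAYS} d")
    spline = make_smoothing_spline(doys, wdrvi)  # lam chosen by GCV
    grid = np.arange(math.ceil(doys[0]), math.floor(doys[-1]) + 1.0)
    values = np.clip(spline(grid), -1.0, 1.0)
    return WdrviSeries(pixel_id=pixel_id, year=year, grid=grid, values=values,
                       alpha=alpha)


def build_shape_model(daily_series, reference_dates, crop="maize"):
    """Average daily WDRVI series (common grid) into a reference shape model."""
    if not daily_series:
        raise InputError("no input series")
    grid = np.asarray(daily_series[0].grid, dtype=float)
    for s in daily_series[1:]:
        if len(s.grid) != len(grid) or not np.array_equal(s.grid, grid):
            raise InputError("input series are not on a common DOY grid")
    curve = np.mean([s.values for s in daily_series], axis=0)
    return ShapeModel(crop=crop, grid=grid, curve=curve,
                      reference_dates=tuple(reference_dates))


def fit_shape_model(model, series, init=FIT_INIT, bounds=FIT_BOUNDS,
                    min_overlap=MIN_SPAN_DAYS, max_nfev=200):
    """Register the reference curve onto a daily series.

    Minimizes the RMSE between ``yscale * h(xscale*x + tshift)`` and the
    series over the days where the transformed argument stays inside the
    model grid (out-of-grid days drop out of the loss). The minimization is
    a bounded Levenberg-Marquardt-type nonlinear least squares
    (trust-region reflective).
    """
    x = np.asarray(series.grid, dtype=float)
    y = np.asarray(series.values, dtype=float)

    def transformed(params):
        xs, ts, ys = params
        arg = xs * x + ts
        inside = (arg >= model.grid[0]) & (arg <= model.grid[-1])
        pred = ys * np.interp(arg, model.grid, model.curve)
        return pred, inside

    x0 = np.asarray(init, dtype=float)
    pred0, inside0 = transformed(x0)
    if inside0.sum() < min_overlap:
        raise InputError(
            f"series/model overlap {int(inside0.sum())} d < {min_overlap} d "
            "at the initial transformation"
        )

    def residuals(params):
        pred, inside = transformed(params)
        return np.where(inside, pred - y, 0.0)

    res = least_squares(residuals, x0, bounds=bounds, max_nfev=max_nfev)
    pred, inside = transformed(res.x)
    n_in = int(inside.sum())
    rmse = float(np.sqrt(np.mean((pred[inside] - y[inside]) ** 2))) if n_in else np.inf
    converged = bool(res.status > 0) and n_in >= min_overlap
    lo, hi = (np.asarray(b, dtype=float) for b in bounds)
    if converged and (np.any(np.isclose(res.x, lo)) or np.any(np.isclose(res.x, hi))):
        logger.warning(
            "pixel %s year %s: shape-model fit at a parameter bound %s",
            series.pixel_id, series.year, tuple(np.round(res.x, 3)),
        )
    return SmfFit(xscale=float(res.x[0]), tshift=float(res.x[1]),
                  yscale=float(res.x[2]), rmse=rmse, converged=converged,
                  iterations=int(res.nfev))


def stage_dates_from_fit(fit, model, stages=SMF_STAGES):
    """Map reference stage dates through the fitted time transformation.

    A reference date ``d0`` is detected at ``x = (d0 - tshift) / xscale``
    (the observation day whose transformed argument hits ``d0``), rounded to
    the nearest day.
    """
    if not fit.converged:
        raise DetectionError("shape-model fit did not converge")
    out = {}
    for k in stages:
        d0 = model.reference_dates[k]
        doy = (d0 - fit.tshift) / fit.xscale
        if not (1 <= doy <= 366):
            raise DetectionError(f"detected stage DOY {doy:.1f} outside [1, 366]")
        out[k] = int(_round_half_up(doy))
    return out


def _cross_up(grid, values, threshold, before):
    """Last upward crossing of ``threshold`` strictly before ``before``."""
    mask = grid < before
    g, v = grid[mask], values[mask]
    below = v[:-1] <= threshold
    above = v[1:] > threshold
    idx = np.nonzero(below & above)[0]
    exact = np.nonzero(v == threshold)[0]
    candidates = []
    for i in idx:
        frac = (threshold - v[i]) / (v[i + 1] - v[i])
        candidates.append(g[i] + frac * (g[i + 1] - g[i]))
    candidates.extend(g[exact])
    if not candidates:
        return None
    return max(candidates)


def _cross_down(grid, values, threshold, after):
    """First downward crossing of ``threshold`` at or after ``after``."""
    mask = grid >= after
    g, v = grid[mask], values[mask]
    above = v[:-1] >= threshold
    below = v[1:] < threshold
    idx = np.nonzero(above & below)[0]
    exact = np.nonzero(v == threshold)[0]
    candidates = []
    for i in idx:
        frac = (v[i] - threshold) / (v[i] - v[i + 1])
        candidates.append(g[i] + frac * (g[i + 1] - g[i]))
    candidates.extend(g[exact])
    if not candidates:
        return None
    return min(candidates)


def detect_threshold_crossings(series, up_threshold, down_threshold, peak_doy):
    """Emergence and maturity dates from WDRVI threshold crossings.

    Emergence is the last upward crossing of ``up_threshold`` before the
    season peak; maturity is the first downward crossing of
    ``down_threshold`` after it. Crossings are located by linear
    interpolation between daily points and rounded to whole days.
    """
    grid = np.asarray(series.grid, dtype=float)
    values = np.asarray(series.values, dtype=float)
    up = _cross_up(grid, values, up_threshold, before=peak_doy)
    if up is None:
        raise DetectionError(
            f"no upward crossing of {up_threshold} before peak DOY {peak_doy:.0f}"
        )
    down = _cross_down(grid, values, down_threshold, after=peak_doy)
    if down is None:
        raise DetectionError(
            f"no downward crossing of {down_threshold} after peak DOY {peak_doy:.0f}"
        )
    return int(_round_half_up(up)), int(_round_half_up(down))


def select_crop_pixels(cdl, min_fraction=MIN_CROP_FRACTION):
    """Boolean mask of pixel-years with crop fraction >= ``min_fraction``.

    ``cdl`` is a DataFrame with a ``crop_fraction`` column in [0, 1]; the
    cutoff is inclusive ("at least 80%").
    """
    frac = cdl["crop_fraction"].to_numpy(dtype=float)
    if np.any((frac < 0) | (frac > 1)):
        raise InputError("crop fractions must lie in [0, 1]")
    return pd.Series(frac >= min_fraction, index=cdl.index)


def detect_pixel_stages(series, model, crop):
    """All four stage dates for one pixel-year (SMF + threshold hybrid).

    Returns a dict with s1..s4 and the fit; raises ``DetectionError`` when
    the fit fails, a crossing is missing, or the stages come out unordered.
    """
    consts = CROP_CONSTANTS[crop]
    fit = fit_shape_model(model, series)
    mid = stage_dates_from_fit(fit, model, stages=SMF_STAGES)
    peak = (model.peak_doy - fit.tshift) / fit.xscale
    s1, s4 = detect_threshold_crossings(
        series, consts["up_threshold"], consts["down_threshold"], peak_doy=peak
    )
    stages = (s1, mid[1], mid[2], s4)
    if any(b <= a for a, b in zip(stages, stages[1:])):
        raise DetectionError(f"unordered stage dates {stages}")
    return {"stages": stages, "fit": fit}


def detect_stages(reflectance, cdl, model, crop, alpha=DEFAULT_ALPHA,
                  min_fraction=MIN_CROP_FRACTION):
    """Per-pixel stage detection over a reflectance table.

    ``reflectance`` columns: pixel_id, county_id, year, doy, ref_b1, ref_b2,
    qc_flag. ``cdl`` columns: pixel_id, year, crop_fraction. Returns a
    DataFrame of pixel-year stage dates plus a run report counting
    exclusions by reason.
    """
    keep = cdl.loc[select_crop_pixels(cdl, min_fraction), ["pixel_id", "year"]]
    refl = reflectance.merge(keep, on=["pixel_id", "year"], how="inner")
    rows = []
    report = {"n_pixel_years": 0, "detected": 0, "excluded": {}}

    def _count(reason):
        report["excluded"][reason] = report["excluded"].get(reason, 0) + 1

    for (pixel, county, year), grp in refl.groupby(
        ["pixel_id", "county_id", "year"], sort=True
    ):
        report["n_pixel_years"] += 1
        try:
            doys, wdrvi = compute_wdrvi(
                grp["doy"], grp["ref_b1"], grp["ref_b2"], grp["qc_flag"], alpha
            )
            series = smooth_daily(doys, wdrvi, pixel_id=pixel, year=year,
                                  alpha=alpha)
            det = detect_pixel_stages(series, model, crop)
        except (QualityError, DetectionError, InputError) as exc:
            _count(type(exc).__name__)
            logger.info("pixel %s year %s excluded: %s", pixel, year, exc)
            continue
        s1, s2, s3, s4 = det["stages"]
        rows.append({
            "pixel_id": pixel, "county_id": county, "year": int(year),
            "s1": s1, "s2": s2, "s3": s3, "s4": s4,
            "rmse": det["fit"].rmse,
        })
        report["detected"] += 1
    return pd.DataFrame(rows), report


def aggregate_to_county(pixel_stages, crop):
    """Average pixel stage dates to county-year records.

    Stage dates are averaged over valid pixels, rounded half-up to whole
    days, and the durations recomputed from the rounded dates; county-years
    whose rounded dates lose strict ordering are excluded and logged.
    """
    records = []
    for (county, year), grp in pixel_stages.groupby(["county_id", "year"]):
        means = [grp[c].mean() for c in ("s1", "s2", "s3", "s4")]
        stages = tuple(int(v) for v in _round_half_up(means))
        try:
            rec = PhenologyRecord(county_id=county, year=int(year), crop=crop,
                                  stages=stages, n_pixels=len(grp))
        except DetectionError as exc:
            logger.info("county %s year %s excluded: %s", county, year, exc)
            continue
        records.append(rec)
    return records


def records_to_frame(records):
    return pd.DataFrame([
        {
            "county_id": r.county_id, "year": r.year, "crop": r.crop,
            "s1": r.stages[0], "s2": r.stages[1], "s3": r.stages[2],
            "s4": r.stages[3], "d1": r.durations[0], "d2": r.durations[1],
            "d3": r.durations[2], "n_pixels": r.n_pixels,
        }
        for r in records
    ])


def interpolate_cpr(week_doys, area_ratios):
    """Reference stage date: 50% crossing of a logistic fit to area ratios.

    Fits ratio(t) = 100 / (1 + exp(-k (t - t50))) by least squares and
    returns t50 rounded to the nearest day. Ratios are percentages in
    [0, 100] and must straddle 50.
    """
    t = np.asarray(week_doys, dtype=float)
    r = np.asarray(area_ratios, dtype=float)
    if np.any((r < 0) | (r > 100)):
        raise InputError("area ratios must lie in [0, 100]")
    if not (r.min() < 50 < r.max() or np.any(r == 50)):
        raise InputError("area ratios never straddle 50%")

    def logistic(x, k, t50):
        return 100.0 / (1.0 + np.exp(-k * (x - t50)))

    # initial guess: crossing from linear interpolation, slope from range
    t50_0 = float(np.interp(50.0, r, t)) if np.all(np.diff(r) >= 0) else float(t.mean())
    popt, _ = curve_fit(logistic, t, r, p0=(0.2, t50_0), maxfev=10000)
    return int(_round_half_up(popt[1]))


def evaluate_rmse(estimated, reference, groups=None):
    """Root mean square difference (days) between paired date vectors.

    With ``groups`` given (same length), returns a dict of per-group RMSEs.
    """
    est = np.asarray(estimated, dtype=float)
    ref = np.asarray(reference, dtype=float)
    if est.size == 0 or est.shape != ref.shape:
        raise InputError("paired date vectors must be nonempty and equal length")
    if groups is None:
        return float(np.sqrt(np.mean((est - ref) ** 2)))
    out = {}
    groups = np.asarray(groups)
    for g in np.unique(groups):
        m = groups == g
        out[g] = float(np.sqrt(np.mean((est[m] - ref[m]) ** 2)))
    return out
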