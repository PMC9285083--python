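"""Duration-resolved weather aggregation and drought/heat exposure classes.

Daily county weather is aggregated into the three phenological durations
D1-D3 bounded by the four detected stage dates (half-open day windows
[S_k, S_{k+1})). Within each county x duration cell, precipitation totals
and mean maximum temperature are standardized across years into the
standardized precipitation anomaly (SPA) and standardized temperature
anomaly (STA),

    x = (x_{y,t} - mean_t) / sd_t,

with the across-year sample standard deviation (ddof 1) and the focal year
included in its own climatology (a leave-one-out variant is available).
PDSI is consumed as a daily input column and averaged over each window.
Exposure categories follow conventional drought-monitor style bins, closed
into half-open intervals so every finite value maps to exactly one class.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import InputError, UndefinedAnomalyError

DURATIONS = ("D1", "D2", "D3")

#: (lower, upper, label) half-open bins [lower, upper); lower bound -inf/inf
#: sentinels close the line. The conventional PDSI labels leave slivers like
#: (-2.0, -1.9) undefined; the round numbers are used as the cut points.
PDSI_BINS = [
    (-np.inf, -4.0, "Extreme Drought"),
    (-4.0, -3.0, "Severe Drought"),
    (-3.0, -2.0, "Moderate Drought"),
    (-2.0, 2.0, "Near Normal"),
    (2.0, 3.0, "Unusual Moist Spell"),
    (3.0, 4.0, "Very Moist Spell"),
    (4.0, np.inf, "Extremely Moist"),
]

SPA_BINS = [
    (-np.inf, -2.0, "Extreme Dry"),
    (-2.0, -0.5, "Moderate Dry"),
    (-0.5, 0.5, "Near Normal"),
    (0.5, 2.5, "Moderate Wet"),
    (2.5, np.inf, "Extreme Wet"),
]

STA_BINS = [
    (-np.inf, -2.0, "Extreme Cold"),
    (-2.0, -0.5, "Moderate Cold"),
    (-0.5, 0.5, "Near Normal"),
    (0.5, 2.5, "Moderate Heat"),
    (2.5, np.inf, "Extreme Heat"),
]

#: Minimum number of years per county x duration for a defined anomaly.
MIN_CLIMATOLOGY_YEARS = 5


def _classify(value, bins, index_name):
    v = float(value)
    if not np.isfinite(v):
        raise InputError(f"non-finite {index_name} value")
    for lo, hi, label in bins:
        if lo <= v < hi:
            return label
    raise InputError(f"{index_name} value {v} matched no bin")  # pragma: no cover


def classify_pdsi(value):
    """Palmer Drought Severity Index category for a finite value."""
    return _classify(value, PDSI_BINS, "PDSI")


def classify_spa(value):
    """Standardized precipitation anomaly category for a finite value."""
    return _classify(value, SPA_BINS, "SPA")


def classify_sta(value):
    """Standardized temperature anomaly category for a finite value."""
    return _classify(value, STA_BINS, "STA")


def _classify_series(values, bins):
    v = np.asarray(values, dtype=float)
    conditions = [(v >= lo) & (v < hi) for lo, hi, _ in bins]
    labels = [label for _, _, label in bins]
    return np.select(conditions, labels, default=None)


def aggregate_duration(weather, record):
    """Aggregate one county-year of daily weather into D1-D3 rows.

    ``weather`` is the daily table for the county-year (columns doy, tmax_c,
    tmin_c, precip_mm, srad_wm2, vpd_kpa, pdsi); ``record`` is the matching
    :class:`~primecrop.phenology.PhenologyRecord`. Temperatures, radiation,
    VPD, and PDSI are averaged over each half-open window [S_k, S_{k+1});
    precipitation is summed.
    """
    doy = weather["doy"].to_numpy()
    s = record.stages
    if doy.min() > s[0] or doy.max() < s[3] - 1:
        raise InputError(
            f"county {record.county_id} year {record.year}: weather does not "
            f"cover stage span [{s[0]}, {s[3]})"
        )
    rows = []
    for k, name in enumerate(DURATIONS):
        lo, hi = s[k], s[k + 1]
        win = weather[(doy >= lo) & (doy < hi)]
        expected = hi - lo
        if len(win) != expected:
            raise InputError(
                f"county {record.county_id} year {record.year} {name}: "
                f"{len(win)} weather days for a {expected}-day window"
            )
        rows.append({
            "county_id": record.county_id,
            "year": record.year,
            "crop": record.crop,
            "duration": name,
            "tmax": win["tmax_c"].mean(),
            "tmin": win["tmin_c"].mean(),
            "srad": win["srad_wm2"].mean(),
            "vpd": win["vpd_kpa"].mean(),
            "precip_total": win["precip_mm"].sum(),
            "pdsi": win["pdsi"].mean(),
        })
    return pd.DataFrame(rows)


def _standardize_panel(df, value_col, leave_one_out=False,
                       min_years=MIN_CLIMATOLOGY_YEARS):
    """Across-year standardized anomaly within each county x duration."""
    out = pd.Series(np.nan, index=df.index)
    for _, grp in df.groupby(["county_id", "duration"], sort=False):
        x = grp[value_col].to_numpy(dtype=float)
        n = len(x)
        if n < min_years:
            raise UndefinedAnomalyError(
                f"{value_col}: only {n} years (< {min_years}) for "
                f"county {grp['county_id'].iloc[0]} {grp['duration'].iloc[0]}"
            )
        if leave_one_out:
            idx = np.arange(n)
            vals = np.empty(n)
            for i in idx:
                rest = np.delete(x, i)
                sd = rest.std(ddof=1)
                if sd == 0:
                    raise UndefinedAnomalyError(
                        f"{value_col}: zero across-year SD for county "
                        f"{grp['county_id'].iloc[0]} {grp['duration'].iloc[0]}"
                    )
                vals[i] = (x[i] - rest.mean()) / sd
        else:
            sd = x.std(ddof=1)
            if sd == 0:
                raise UndefinedAnomalyError(
                    f"{value_col}: zero across-year SD for county "
                    f"{grp['county_id'].iloc[0]} {grp['duration'].iloc[0]}"
                )
            vals = (x - x.mean()) / sd
        out.loc[grp.index] = vals
    return out.to_numpy()


def compute_spa(duration_climate, leave_one_out=False,
                min_years=MIN_CLIMATOLOGY_YEARS):
    """Standardized precipitation anomaly per county-year-duration."""
    return _standardize_panel(duration_climate, "precip_total", leave_one_out,
                              min_years)


def compute_sta(duration_climate, leave_one_out=False,
                min_years=MIN_CLIMATOLOGY_YEARS):
    """Standardized (duration-mean Tmax) temperature anomaly."""
    return _standardize_panel(duration_climate, "tmax", leave_one_out,
                              min_years)


def build_duration_climate(weather, records, leave_one_out=False):
    """Full duration-climate table for a set of county-year records.

    ``weather`` is the stacked daily table for all counties and years
    (must contain county_id and either a ``year`` column or dates); returns
    one row per county-year-duration with aggregates, SPA/STA values, and
    PDSI/SPA/STA classes.
    """
    if "year" not in weather.columns:
        weather = weather.assign(year=pd.to_datetime(weather["date"]).dt.year)
    parts = []
    grouped = weather.groupby(["county_id", "year"], sort=True)
    for rec in records:
        try:
            daily = grouped.get_group((rec.county_id, rec.year))
        except KeyError:
            raise InputError(
                f"no weather for county {rec.county_id} year {rec.year}"
            ) from None
        parts.append(aggregate_duration(daily, rec))
    table = pd.concat(parts, ignore_index=True)
    table["spa"] = compute_spa(table, leave_one_out)
    table["sta"] = compute_sta(table, leave_one_out)
    table["pdsi_class"] = _classify_series(table["pdsi"], PDSI_BINS)
    table["spa_class"] = _classify_series(table["spa"], SPA_BINS)
    table["sta_class"] = _classify_series(table["sta"], STA_BINS)
    return table
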