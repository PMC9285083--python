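"""County-year yield anomalies from panel fixed-effects and trend models.

Three expectation models are fitted and subtracted from observed yields:

* ``C1`` — panel OLS with county fixed effects, a common linear year trend,
  and duration-resolved weather covariates (Tmax, Tmin, Srad, VPD for each
  of D1-D3). Precipitation is deliberately excluded so the drought signal
  survives in the residual.
* ``C2`` — an independent linear trend per county (intercept + slope on
  year); only technology/agronomy trend is removed.
* ``Ctemp`` — as C1 but with Tmin, Srad, VPD, and precipitation totals as
  covariates, excluding Tmax so the heat signal survives in the residual.

Anomalies are observed minus fitted yields (Mg/Ha).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import CollinearityError, InputError
from .climate import DURATIONS

logger = logging.getLogger(__name__)

C1_VARIABLES = ("tmax", "tmin", "srad", "vpd")
CTEMP_VARIABLES = ("tmin", "srad", "vpd", "precip_total")
VARIANTS = ("C1", "C2", "Ctemp")


@dataclass
class PanelFit:
    """Fitted panel model: coefficients, county intercepts, residuals."""

    variant: str
    trend: float  # Mg/Ha per year
    coefficients: dict  # (variable, duration) -> slope
    county_intercepts: dict
    fitted: pd.Series  # indexed like the panel rows
    residuals: pd.Series
    r2: float
    n_obs: int


def build_panel(yields, duration_climate):
    """Wide panel: one row per county-year with per-duration covariates.

    Joins the yield table (county_id, year, crop, yield_mg_ha) with the
    duration-climate table; covariate columns are named ``<var>_d<j>``.
    Rows with any missing covariate are dropped.
    """
    wide = duration_climate.pivot_table(
        index=["county_id", "year"], columns="duration",
        values=["tmax", "tmin", "srad", "vpd", "precip_total"],
    )
    wide.columns = [f"{var}_d{DURATIONS.index(dur) + 1}" for var, dur in wide.columns]
    panel = yields.set_index(["county_id", "year"]).join(wide, how="inner")
    panel = panel.dropna()
    if panel.index.get_level_values("county_id").nunique() < 2:
        raise InputError("panel needs at least 2 counties")
    year_counts = panel.groupby(level="county_id").size()
    if (year_counts < 2).any():
        bad = year_counts[year_counts < 2].index.tolist()
        raise InputError(f"counties with < 2 years in the panel: {bad}")
    return panel.reset_index()


def _design(panel, variables):
    y0 = panel["year"].min()
    cols, names = [], []
    cols.append((panel["year"] - y0).to_numpy(dtype=float))
    names.append("trend")
    for var in variables:
        for j in (1, 2, 3):
            col = f"{var}_d{j}"
            if col not in panel.columns:
                raise InputError(f"panel is missing covariate column {col}")
            v = panel[col].to_numpy(dtype=float)
            if np.all(np.isnan(v)) or len(v) == 0:
                raise InputError(f"covariate column {col} is empty")
            cols.append(v)
            names.append(col)
    dummies = pd.get_dummies(panel["county_id"], prefix="county", dtype=float)
    X = np.column_stack(cols + [dummies.to_numpy()])
    names = names + list(dummies.columns)
    return X, names


def _check_rank(X, names):
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the offending columns: exact duplicates / constants first
        offenders = []
        for i in range(X.shape[1]):
            for k in range(i + 1, X.shape[1]):
                if np.allclose(X[:, i], X[:, k]):
                    offenders.extend([names[i], names[k]])
        if not offenders:
            offenders = [n for i, n in enumerate(names) if np.ptp(X[:, i]) == 0]
        raise CollinearityError(sorted(set(offenders)) or names)


def _fit_panel(panel, variables, variant):
    X, names = _design(panel, variables)
    y = panel["yield_mg_ha"].to_numpy(dtype=float)
    _check_rank(X, names)
    res = sm.OLS(y, X).fit()
    params = dict(zip(names, res.params))
    coefficients = {}
    for var in variables:
        for j in (1, 2, 3):
            coefficients[(var, f"D{j}")] = params[f"{var}_d{j}"]
    county_intercepts = {
        n.split("county_", 1)[1]: v for n, v in params.items()
        if n.startswith("county_")
    }
    idx = pd.MultiIndex.from_frame(panel[["county_id", "year"]])
    fitted = pd.Series(res.fittedvalues, index=idx)
    resid = pd.Series(res.resid, index=idx)
    return PanelFit(
        variant=variant, trend=params["trend"], coefficients=coefficients,
        county_intercepts=county_intercepts, fitted=fitted, residuals=resid,
        r2=float(res.rsquared), n_obs=int(res.nobs),
    )


def fit_panel_c1(panel):
    """Full-weather panel fixed-effects fit (strategy C1)."""
    return _fit_panel(panel, C1_VARIABLES, "C1")


def fit_panel_temp(panel):
    """Temperature-variant panel fit (Tmax excluded, precipitation added)."""
    return _fit_panel(panel, CTEMP_VARIABLES, "Ctemp")


def fit_trend_c2(panel, min_years=3):
    """Independent per-county linear yield trend (strategy C2).

    Counties with fewer than ``min_years`` observations are excluded and
    logged. Returns a :class:`PanelFit` whose coefficients dict maps
    county -> (intercept, slope).
    """
    fitted_parts, resid_parts, coefs = [], [], {}
    for county, grp in panel.groupby("county_id"):
        if len(grp) < min_years:
            logger.info("county %s excluded from C2: only %d years",
                        county, len(grp))
            continue
        t = grp["year"].to_numpy(dtype=float)
        y = grp["yield_mg_ha"].to_numpy(dtype=float)
        slope, intercept = np.polyfit(t, y, 1)
        pred = intercept + slope * t
        idx = pd.MultiIndex.from_frame(grp[["county_id", "year"]])
        fitted_parts.append(pd.Series(pred, index=idx))
        resid_parts.append(pd.Series(y - pred, index=idx))
        coefs[county] = (float(intercept), float(slope))
    if not fitted_parts:
        raise InputError("no county had enough years for a trend fit")
    fitted = pd.concat(fitted_parts)
    resid = pd.concat(resid_parts)
    y_all = panel.set_index(["county_id", "year"])["yield_mg_ha"].loc[fitted.index]
    ss_res = float((resid**2).sum())
    ss_tot = float(((y_all - y_all.mean()) ** 2).sum())
    return PanelFit(
        variant="C2", trend=float(np.mean([s for _, s in coefs.values()])),
        coefficients=coefs, county_intercepts={}, fitted=fitted,
        residuals=resid, r2=1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan,
        n_obs=len(fitted),
    )


def compute_anomaly(panel, fit):
    """Anomaly records (observed minus fitted) for every fitted panel row."""
    idx = pd.MultiIndex.from_frame(panel[["county_id", "year"]])
    obs = pd.Series(panel["yield_mg_ha"].to_numpy(dtype=float), index=idx)
    missing = obs.index.difference(fit.fitted.index)
    if fit.variant != "C2" and len(missing):
        raise InputError(f"{len(missing)} panel rows without fitted values")
    common = obs.index.intersection(fit.fitted.index)
    anomaly = obs.loc[common] - fit.fitted.loc[common]
    out = anomaly.rename("anomaly_mg_ha").reset_index()
    out["crop"] = panel["crop"].iloc[0] if "crop" in panel.columns else ""
    out["variant"] = fit.variant
    return out[["county_id", "year", "crop", "variant", "anomaly_mg_ha"]]


def fit_variant(panel, variant):
    """Dispatch: fit one of C1 / C2 / Ctemp on a built panel."""
    if variant == "C1":
        return fit_panel_c1(panel)
    if variant == "C2":
        return fit_trend_c2(panel)
    if variant == "Ctemp":
        return fit_panel_temp(panel)
    raise InputError(f"unknown variant {variant!r} (expected one of {VARIANTS})")
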