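"""Priming/nonpriming/control group delineation and mitigation statistics.

County-years are grouped by their drought (PDSI or SPA) or heat (STA)
exposure across the three phenological durations: the *priming* group saw
stress in both D1 and D3 with near-normal D2, the *nonpriming* group saw the
same late stress without the early exposure, and the *control* group saw no
stress in any duration. Group responses (yield anomalies, raw or simulated
yields) are compared with a Welch two-sample t-test (priming vs nonpriming)
and a one-way ANOVA across the three groups, and summarized by the
mitigation arithmetic

    mitigation_abs  = mean(priming) - mean(nonpriming)
    loss_nonpriming = mean(control) - mean(nonpriming)
    mitigation_frac = mitigation_abs / loss_nonpriming.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError, InsufficientDataError

GROUP_ORDER = ("priming", "nonpriming", "control")

_INF = math.inf

#: Exposure windows (lo, hi), strict on both bounds, per duration, for each
#: index. STA windows follow the stated hypothesis of early *heat* exposure
#: (priming D1 requires STA above +0.5, not merely above -0.5).
DEFAULT_RULES = {
    "pdsi": {
        "priming": ((-_INF, -2.0), (-2.0, 2.0), (-_INF, -2.0)),
        "nonpriming": ((-2.0, 2.0), (-2.0, 2.0), (-_INF, -2.0)),
        "control": ((-2.0, 2.0), (-2.0, 2.0), (-2.0, 2.0)),
    },
    "spa": {
        "priming": ((-2.0, -0.5), (-0.5, 0.5), (-2.0, -0.5)),
        "nonpriming": ((-0.5, 0.5), (-0.5, 0.5), (-2.0, -0.5)),
        "control": ((-0.5, 0.5), (-0.5, 0.5), (-0.5, 0.5)),
    },
    "sta": {
        "priming": ((0.5, 2.0), (-0.5, 0.5), (0.5, 2.0)),
        "nonpriming": ((-0.5, 0.5), (-0.5, 0.5), (0.5, 2.0)),
        "control": ((-0.5, 0.5), (-0.5, 0.5), (-0.5, 0.5)),
    },
}

#: Variant of the PDSI rules where the nonpriming D1 window is (0, 2)
#: rather than (-2, 2) (the narrower reading of the grouping procedure).
PDSI_TEXT_VARIANT = {
    "priming": ((-_INF, -2.0), (-2.0, 2.0), (-_INF, -2.0)),
    "nonpriming": ((0.0, 2.0), (-2.0, 2.0), (-_INF, -2.0)),
    "control": ((-2.0, 2.0), (-2.0, 2.0), (-2.0, 2.0)),
}


@dataclass(frozen=True)
class GroupRules:
    """Per-duration exposure windows for each group under one index."""

    index: str  # pdsi | spa | sta
    windows: dict  # group -> 3 x (lo, hi), strict bounds

    def __post_init__(self):
        for group in GROUP_ORDER:
            if group not in self.windows:
                raise InputError(f"missing windows for group {group!r}")
            if len(self.windows[group]) != 3:
                raise InputError(f"group {group!r} needs one window per duration")
        pw, nw = self.windows["priming"], self.windows["nonpriming"]
        if tuple(pw[1]) != tuple(nw[1]) or tuple(pw[2]) != tuple(nw[2]):
            raise InputError(
                "priming and nonpriming may differ only in the D1 window"
            )

    @classmethod
    def default(cls, index, pdsi_text_variant=False):
        index = index.lower()
        if index not in DEFAULT_RULES:
            raise InputError(f"unknown exposure index {index!r}")
        windows = PDSI_TEXT_VARIANT if (index == "pdsi" and pdsi_text_variant) \
            else DEFAULT_RULES[index]
        return cls(index=index, windows=windows)

    def match(self, values):
        """First matching group for the (D1, D2, D3) index values, or
        ``"excluded"``. Bounds are strict: values exactly on a bound fall
        outside the window."""
        v = tuple(float(x) for x in values)
        if len(v) != 3 or not all(np.isfinite(v)):
            raise InputError("need finite index values for all three durations")
        for group in GROUP_ORDER:
            if all(lo < x < hi for x, (lo, hi) in zip(v, self.windows[group])):
                return group
        return "excluded"


@dataclass
class PrimingResult:
    """Group statistics, tests, and mitigation metrics for one comparison."""

    index: str
    group_stats: dict  # group -> {n, mean, sd}
    t_stat: float
    t_pvalue: float
    anova_f: float
    anova_pvalue: float
    mitigation_abs: float
    loss_nonpriming: float
    mitigation_frac: float  # NaN when loss_nonpriming <= 0
    pct_of_mean_yield: float = float("nan")
    notes: list = field(default_factory=list)

    def to_dict(self):
        out = {
            "index": self.index,
            "groups": {g: dict(s) for g, s in self.group_stats.items()},
            "welch_t": {"t": self.t_stat, "p": self.t_pvalue},
            "anova": {"F": self.anova_f, "p": self.anova_pvalue},
            "mitigation_abs_mg_ha": self.mitigation_abs,
            "loss_nonpriming_mg_ha": self.loss_nonpriming,
            "mitigation_frac": self.mitigation_frac,
            "pct_of_mean_yield": self.pct_of_mean_yield,
            "notes": self.notes,
        }
        return out


def assign_groups(duration_climate, rules):
    """Group label per county-year from its three duration exposure values.

    ``duration_climate`` must carry a column named after ``rules.index``
    (pdsi / spa / sta) and rows for all three durations; county-years with a
    missing duration are labelled excluded with a reason.
    """
    col = rules.index
    if col not in duration_climate.columns:
        raise InputError(f"duration climate lacks a {col!r} column")
    wide = duration_climate.pivot_table(
        index=["county_id", "year"], columns="duration", values=col,
    )
    rows = []
    for (county, year), row in wide.iterrows():
        vals = [row.get(f"D{k}") for k in (1, 2, 3)]
        if any(v is None or not np.isfinite(v) for v in vals):
            rows.append({"county_id": county, "year": year,
                         "label": "excluded", "reason": "missing duration"})
            continue
        rows.append({"county_id": county, "year": year,
                     "label": rules.match(vals), "reason": ""})
    return pd.DataFrame(rows)


def mitigation_metrics(mean_control, mean_priming, mean_nonpriming,
                       mean_yield=None):
    """Mitigation arithmetic from the three group means.

    Returns a dict with ``mitigation_abs`` (priming minus nonpriming mean,
    Mg/Ha), ``loss_nonpriming`` (control minus nonpriming), the mitigated
    fraction of the loss, and — when ``mean_yield`` is given —
    the absolute mitigation as a percentage of the mean yield.
    """
    mitigation_abs = mean_priming - mean_nonpriming
    loss = mean_control - mean_nonpriming
    notes = []
    if loss > 0:
        frac = mitigation_abs / loss
    else:
        frac = float("nan")
        notes.append("mitigation fraction undefined: nonpriming group shows "
                     "no loss relative to control")
    out = {
        "mitigation_abs": mitigation_abs,
        "loss_nonpriming": loss,
        "mitigation_frac": frac,
        "notes": notes,
    }
    if mean_yield is not None:
        if mean_yield <= 0:
            raise InputError("mean yield must be positive")
        out["pct_of_mean_yield"] = 100.0 * mitigation_abs / mean_yield
    else:
        out["pct_of_mean_yield"] = float("nan")
    return out


def compare_groups(responses, labels, index="pdsi", mean_yield=None,
                   min_group_size=2):
    """Welch t-test, ANOVA, and mitigation metrics over labelled responses.

    ``responses`` and ``labels`` are aligned sequences; only the three
    analysis groups enter the tests (excluded labels are ignored).
    """
    responses = np.asarray(responses, dtype=float)
    labels = np.asarray(labels)
    samples = {}
    for group in GROUP_ORDER:
        vals = responses[labels == group]
        if len(vals) < min_group_size:
            raise InsufficientDataError(
                f"group {group!r} has {len(vals)} observations "
                f"(< {min_group_size})"
            )
        samples[group] = vals
    stats_by_group = {
        g: {"n": int(len(v)), "mean": float(v.mean()),
            "sd": float(v.std(ddof=1))}
        for g, v in samples.items()
    }
    t_res = stats.ttest_ind(samples["priming"], samples["nonpriming"],
                            equal_var=False)
    f_res = stats.f_oneway(*(samples[g] for g in GROUP_ORDER))
    metrics = mitigation_metrics(
        stats_by_group["control"]["mean"], stats_by_group["priming"]["mean"],
        stats_by_group["nonpriming"]["mean"], mean_yield=mean_yield,
    )
    return PrimingResult(
        index=index, group_stats=stats_by_group,
        t_stat=float(t_res.statistic), t_pvalue=float(t_res.pvalue),
        anova_f=float(f_res.statistic), anova_pvalue=float(f_res.pvalue),
        mitigation_abs=metrics["mitigation_abs"],
        loss_nonpriming=metrics["loss_nonpriming"],
        mitigation_frac=metrics["mitigation_frac"],
        pct_of_mean_yield=metrics["pct_of_mean_yield"],
        notes=metrics["notes"],
    )


def county_priming_frequency(labels_df):
    """Number of priming-labelled years per county."""
    counts = (
        labels_df[labels_df["label"] == "priming"]
        .groupby("county_id").size()
    )
    all_counties = labels_df["county_id"].unique()
    counts = counts.reindex(all_counties, fill_value=0).sort_index()
    return counts.rename("n_priming_years").reset_index()


def lai_group_stats(lai_table, labels_df, alpha=0.05):
    """Leaf-area-index statistics per group x duration with pairwise flags.

    ``lai_table`` columns: county_id, year, duration, lai (>= 0). Returns a
    stats frame (group, duration, n, mean, median, sd) and a pairwise frame
    with Welch p-values and significance flags at ``alpha``. Group-duration
    cells with fewer than two observations are omitted with a note.
    """
    if (lai_table["lai"] < 0).any():
        raise InputError("LAI values must be nonnegative")
    merged = lai_table.merge(labels_df[["county_id", "year", "label"]],
                             on=["county_id", "year"])
    merged = merged[merged["label"].isin(GROUP_ORDER)]
    rows, notes = [], []
    cells = {}
    for (group, dur), grp in merged.groupby(["label", "duration"]):
        vals = grp["lai"].to_numpy(dtype=float)
        if len(vals) < 2:
            notes.append(f"{group}/{dur} omitted: n={len(vals)}")
            continue
        cells[(group, dur)] = vals
        rows.append({
            "group": group, "duration": dur, "n": len(vals),
            "mean": float(np.mean(vals)), "median": float(np.median(vals)),
            "sd": float(np.std(vals, ddof=1)),
        })
    pair_rows = []
    durations = sorted({d for _, d in cells})
    for dur in durations:
        for i, g1 in enumerate(GROUP_ORDER):
            for g2 in GROUP_ORDER[i + 1:]:
                if (g1, dur) in cells and (g2, dur) in cells:
                    a, b = cells[(g1, dur)], cells[(g2, dur)]
                    if np.ptp(a) == 0 and np.ptp(b) == 0 and a.mean() == b.mean():
                        p = 1.0
                    else:
                        p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
                    pair_rows.append({
                        "duration": dur, "group_a": g1, "group_b": g2,
                        "pvalue": p, "significant": bool(p < alpha),
                    })
    return pd.DataFrame(rows), pd.DataFrame(pair_rows), notes
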