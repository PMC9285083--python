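"""End-to-end orchestration of the priming analysis stages.

simulate -> phenology -> duration climate -> yield anomaly -> priming
grouping and mitigation statistics. Each stage is a thin function over the
corresponding module so the CLI, the tests, and the demo share one code
path.
"""

from __future__ import annotations

import logging

from . import anomaly as anomaly_mod
from . import climate as climate_mod
from . import phenology as phen_mod
from . import priming as priming_mod
from . import synthetic as synth_mod

logger = logging.getLogger(__name__)


def run_phenology(reflectance, cdl, model, crop):
    """Detect pixel stages and aggregate to county-year records."""
    pixel_stages, report = phen_mod.detect_stages(reflectance, cdl, model, crop)
    records = phen_mod.aggregate_to_county(pixel_stages, crop)
    table = phen_mod.records_to_frame(records)
    return table, records, report


def run_climate(weather, records):
    return climate_mod.build_duration_climate(weather, records)


def run_anomaly(yields, duration_climate, variant="C2"):
    panel = anomaly_mod.build_panel(yields, duration_climate)
    fit = anomaly_mod.fit_variant(panel, variant)
    return anomaly_mod.compute_anomaly(panel, fit), fit


def run_priming(anomalies, duration_climate, index="pdsi", mean_yield=None,
                pdsi_text_variant=False):
    rules = priming_mod.GroupRules.default(index,
                                           pdsi_text_variant=pdsi_text_variant)
    labels = priming_mod.assign_groups(duration_climate, rules)
    merged = anomalies.merge(labels[["county_id", "year", "label"]],
                             on=["county_id", "year"])
    result = priming_mod.compare_groups(
        merged["anomaly_mg_ha"], merged["label"], index=index,
        mean_yield=mean_yield,
    )
    frequency = priming_mod.county_priming_frequency(labels)
    return result, labels, frequency


def run_demo(config=None, variant="C2", index="pdsi"):
    """One-command synthetic demonstration of the full pipeline.

    Returns a report dict with per-stage row counts, the panel/anomaly
    summary, and the priming mitigation statistics, plus the intermediate
    tables for inspection.
    """
    config = config or synth_mod.SimulationConfig()
    bundle = synth_mod.make_scenario(config)
    model = synth_mod.reference_shape_model(config)
    phen_table, records, phen_report = run_phenology(
        bundle.reflectance, bundle.cdl, model, config.crop
    )
    duration_climate = run_climate(bundle.weather, records)
    anomalies, fit = run_anomaly(bundle.yields, duration_climate, variant)
    mean_yield = float(bundle.yields["yield_mg_ha"].mean())
    result, labels, frequency = run_priming(
        anomalies, duration_climate, index=index, mean_yield=mean_yield
    )
    report = {
        "seed": config.seed,
        "crop": config.crop,
        "variant": variant,
        "index": index,
        "n_counties": config.n_counties,
        "n_years": len(config.years),
        "rows": {
            "reflectance": len(bundle.reflectance),
            "weather": len(bundle.weather),
            "yields": len(bundle.yields),
            "phenology": len(phen_table),
            "duration_climate": len(duration_climate),
            "anomalies": len(anomalies),
        },
        "phenology_report": phen_report,
        "panel_r2": fit.r2,
        "mean_yield_mg_ha": mean_yield,
        "priming": result.to_dict(),
    }
    intermediates = {
        "bundle": bundle, "model": model, "phenology": phen_table,
        "records": records, "duration_climate": duration_climate,
        "anomalies": anomalies, "labels": labels, "frequency": frequency,
        "fit": fit,
    }
    return report, intermediates
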