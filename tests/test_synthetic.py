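"""Generator tests: determinism, ground-truth consistency, injected effects."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from primecrop import climate as cl
from primecrop import phenology as phen
from primecrop import synthetic as synth
from primecrop.errors import ConfigError


class TestConfigValidation:
    @pytest.mark.parametrize("kwargs", [
        {"missing_rate": 1.0},
        {"missing_rate": -0.1},
        {"priming_mitigation_frac": 1.2},
        {"stage_date_means": (200.0, 150.0, 240.0, 265.0)},
        {"composite_noise_sd": -1.0},
        {"crop": "wheat"},
        {"group_proportions": {"control": 0.5, "nonpriming": 0.2,
                               "priming": 0.2, "other": 0.0}},
    ])
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ConfigError):
            synth.SimulationConfig(**kwargs)


class TestWeather:
    def test_seeded_determinism(self, small_config):
        a = synth.simulate_weather(small_config, 1, 2003)
        b = synth.simulate_weather(small_config, 1, 2003)
        pd.testing.assert_frame_equal(a, b)

    def test_physical_bounds(self, small_config):
        w = synth.simulate_weather(small_config, 0, 2005)
        assert len(w) == 365
        assert (w["tmax_c"] >= w["tmin_c"]).all()
        assert (w[["precip_mm", "srad_wm2", "vpd_kpa"]] >= 0).all().all()
        assert w["pdsi"].between(-6, 6).all()

    def test_zero_noise_matches_climatology(self):
        cfg = synth.SimulationConfig(seed=1, n_counties=2)
        for spec in cfg.weather_climatology.values():
            spec["sd"] = 0.0
        cfg.county_offset_frac = 0.0
        w = synth.simulate_weather(cfg, 0, 2000)
        clim = cfg.weather_climatology["tmax"]
        expected = clim["mean"] + clim["amp"] * np.cos(
            2 * np.pi * (w["doy"] - 199) / 365.25
        )
        np.testing.assert_allclose(w["tmax_c"], expected, atol=1e-12)

    def test_scaled_late_precip_depresses_drought_index(self, small_config):
        normal = synth.simulate_weather(small_config, 0, 2004)
        dry = synth.simulate_weather(small_config, 0, 2004,
                                     precip_scales=[(225.0, 265.0, 0.0)])
        late = (normal["doy"] >= 240) & (normal["doy"] < 265)
        assert dry.loc[late, "pdsi"].mean() < normal.loc[late, "pdsi"].mean() - 1.0

    def test_unknown_county_or_year_rejected(self, small_config):
        with pytest.raises(Exception):
            synth.simulate_weather(small_config, 99, 2004)
        with pytest.raises(Exception):
            synth.simulate_weather(small_config, 0, 1980)


class TestReflectance:
    def test_noise_free_roundtrip(self):
        cfg = synth.SimulationConfig(seed=2, composite_noise_sd=0.0,
                                     missing_rate=0.0)
        dates = np.array(cfg.stage_date_means) + 4.0
        refl = synth.simulate_reflectance(dates, cfg,
                                          rng=np.random.default_rng(0))
        doys, wdrvi = phen.compute_wdrvi(refl["doy"], refl["ref_b1"],
                                         refl["ref_b2"], refl["qc_flag"])
        curve = synth.pixel_canopy_curve(dates, cfg.crop)
        assert np.abs(wdrvi - curve(doys)).max() <= 1e-12

    def test_missing_rate_flags_binomial(self):
        cfg = synth.SimulationConfig(seed=3, missing_rate=0.2)
        dates = np.array(cfg.stage_date_means)
        total, n_comp = 0, 0
        for s in range(100):
            refl = synth.simulate_reflectance(
                dates, cfg, rng=np.random.default_rng(s)
            )
            total += (refl["qc_flag"] == "bad").sum()
            n_comp += len(refl)
        lo, hi = stats.binom.interval(0.99, n_comp, 0.2)
        assert lo <= total <= hi

    def test_winter_composites_below_emergence_threshold(self):
        cfg = synth.SimulationConfig(seed=4, composite_noise_sd=0.0,
                                     missing_rate=0.0)
        refl = synth.simulate_reflectance(
            np.array(cfg.stage_date_means), cfg, rng=np.random.default_rng(0)
        )
        _, wdrvi = phen.compute_wdrvi(refl["doy"], refl["ref_b1"],
                                      refl["ref_b2"])
        winter = (refl["doy"] < 60) | (refl["doy"] > 330)
        assert (wdrvi[winter.to_numpy()] < -0.68).all()


def _true_climate(bundle, config):
    records = []
    for row in bundle.truth.county_stages.itertuples(index=False):
        stages = tuple(int(np.floor(v + 0.5))
                       for v in (row.s1, row.s2, row.s3, row.s4))
        records.append(phen.PhenologyRecord(
            county_id=row.county_id, year=row.year, crop=config.crop,
            stages=stages, n_pixels=config.pixels_per_county))
    return cl.build_duration_climate(bundle.weather, records)


class TestYields:
    def _yields_by_label(self, cfg):
        bundle = synth.make_scenario(cfg)
        merged = bundle.yields.merge(bundle.truth.labels,
                                     on=["county_id", "year"])
        return merged

    def test_null_mitigation_equalizes_priming_and_nonpriming(self):
        cfg = synth.SimulationConfig(
            seed=11, n_counties=30, priming_mitigation_frac=0.0,
            yield_noise_sd=0.0, county_intercept_sd=0.0,
            weather_sensitivities={k: (0.0, 0.0, 0.0)
                                   for k in ("tmax", "tmin", "srad", "vpd")},
        )
        m = self._yields_by_label(cfg)
        detr = m["yield_mg_ha"] - cfg.trend_slope * (m["year"] - min(cfg.years))
        means = detr.groupby(m["label"]).mean()
        assert abs(means["priming"] - means["nonpriming"]) < 1e-9

    def test_drought_loss_exact_without_noise(self):
        cfg = synth.SimulationConfig(
            seed=12, n_counties=20, yield_noise_sd=0.0,
            county_intercept_sd=0.0, priming_mitigation_frac=0.0,
            weather_sensitivities={k: (0.0, 0.0, 0.0)
                                   for k in ("tmax", "tmin", "srad", "vpd")},
        )
        m = self._yields_by_label(cfg)
        detr = m["yield_mg_ha"] - cfg.trend_slope * (m["year"] - min(cfg.years))
        means = detr.groupby(m["label"]).mean()
        assert means["control"] - means["nonpriming"] == pytest.approx(
            cfg.drought_loss, abs=1e-9
        )

    def test_reference_scale_mitigation_difference(self):
        # loss 0.55 with 67.3% mitigation -> priming-nonpriming gap 0.37 Mg/Ha
        cfg = synth.SimulationConfig(
            seed=13, n_counties=60, drought_loss=0.55,
            priming_mitigation_frac=0.673, yield_noise_sd=0.0,
            county_intercept_sd=0.0,
            weather_sensitivities={k: (0.0, 0.0, 0.0)
                                   for k in ("tmax", "tmin", "srad", "vpd")},
        )
        m = self._yields_by_label(cfg)
        detr = m["yield_mg_ha"] - cfg.trend_slope * (m["year"] - min(cfg.years))
        means = detr.groupby(m["label"]).mean()
        assert means["priming"] - means["nonpriming"] == pytest.approx(
            0.37, abs=0.01
        )

    def test_excessive_loss_raises(self, small_bundle, small_config):
        cfg = synth.SimulationConfig(seed=7, n_counties=8, pixels_per_county=2,
                                     drought_loss=50.0)
        climate = _true_climate(small_bundle, small_config)
        with pytest.raises(ConfigError):
            synth.simulate_yields(cfg, climate, small_bundle.truth.labels)


class TestScenario:
    def test_smoke_and_keys_consistent(self, small_bundle, small_config):
        b = small_bundle
        assert set(b.yields["county_id"]) <= set(range(small_config.n_counties))
        n_cy = small_config.n_counties * len(small_config.years)
        assert len(b.yields) == n_cy
        assert len(b.truth.labels) == n_cy
        assert (b.yields["yield_mg_ha"] > 0).all()

    def test_label_proportions(self):
        cfg = synth.SimulationConfig(seed=21, n_counties=40)
        bundle = synth.make_scenario(cfg)
        counts = bundle.truth.labels["label"].value_counts(normalize=True)
        for group, p in cfg.group_proportions.items():
            if p > 0:
                assert counts.get(group, 0.0) == pytest.approx(p, abs=0.06)

    def test_mitigation_component_only_for_priming(self, small_bundle):
        comp = small_bundle.truth.components.merge(
            small_bundle.truth.labels, on=["county_id", "year"]
        )
        assert (comp.loc[comp["label"] != "priming", "mitigation"] == 0).all()
        assert (comp.loc[comp["label"] == "priming", "mitigation"] > 0).all()

    def test_realized_classification_matches_intent(self, small_bundle,
                                                    small_config):
        """Scenario labels are recoverable from the realized drought index
        at the true stage dates for nearly all county-years."""
        from primecrop import priming as pr
        climate = _true_climate(small_bundle, small_config)
        assigned = pr.assign_groups(climate, pr.GroupRules.default("pdsi"))
        merged = assigned.merge(small_bundle.truth.labels,
                                on=["county_id", "year"],
                                suffixes=("_est", "_true"))
        match = (merged["label_est"] == merged["label_true"]).mean()
        assert match >= 0.95

    def test_cpr_ratios_nondecreasing(self, small_bundle):
        for (_, _, _), grp in small_bundle.cpr.groupby(
            ["year", "stage", "state_id"]
        ):
            r = grp.sort_values("week_doy")["area_ratio"].to_numpy()
            assert (np.diff(r) >= -1e-9).all()

    def test_byte_identical_reruns(self, small_config, tmp_path):
        a = synth.make_scenario(small_config)
        b = synth.make_scenario(small_config)
        for name in ("reflectance", "weather", "yields", "cdl", "cpr"):
            pd.testing.assert_frame_equal(getattr(a, name), getattr(b, name))
        a.write(tmp_path / "a")
        b.write(tmp_path / "b")
        for f in (tmp_path / "a").iterdir():
            assert f.read_bytes() == (tmp_path / "b" / f.name).read_bytes()
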