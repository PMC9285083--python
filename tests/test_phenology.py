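"""Stage-detection tests: WDRVI arithmetic, smoothing, registration,
threshold crossings, aggregation, and validation utilities."""

import numpy as np
import pandas as pd
import pytest

from primecrop import phenology as phen
from primecrop import synthetic as synth
from primecrop.errors import DetectionError, InputError, QualityError


class TestComputeWdrvi:
    @pytest.mark.parametrize("b1, b2, expected", [
        (0.05, 0.45, -0.005 / 0.095),  # hand arithmetic
        (0.045, 0.45, 0.0),  # numerator zero (b1 == alpha*b2)
        (0.0, 0.4, 1.0),  # upper bound
    ])
    def test_values(self, b1, b2, expected):
        _, w = phen.compute_wdrvi([100], [b1], [b2])
        assert w[0] == pytest.approx(expected, abs=1e-12)

    def test_bad_flags_dropped(self):
        doys, w = phen.compute_wdrvi(
            [1, 9, 17], [0.1, 0.1, 0.1], [0.4, 0.4, 0.4],
            qc_flag=["good", "bad", "good"],
        )
        assert list(doys) == [1, 17]

    def test_all_bad_raises(self):
        with pytest.raises(QualityError):
            phen.compute_wdrvi([1], [0.1], [0.4], qc_flag=["bad"])

    def test_nonpositive_alpha_raises(self):
        with pytest.raises(InputError):
            phen.compute_wdrvi([1], [0.1], [0.4], alpha=0.0)


class TestSmoothDaily:
    def _composites(self, maize_model, noise=0.0, drop=None, rng=None):
        doys = np.arange(97.0, 330.0, 8.0)
        vals = np.interp(doys, maize_model.grid, maize_model.curve)
        if noise and rng is not None:
            vals = vals + rng.normal(0, noise, len(vals))
        if drop is not None:
            keep = np.ones(len(doys), dtype=bool)
            keep[drop] = False
            doys, vals = doys[keep], vals[keep]
        return doys, vals

    def test_interpolation_fidelity(self, maize_model):
        doys, vals = self._composites(maize_model)
        series = phen.smooth_daily(doys, vals)
        assert np.abs(series(doys) - vals).max() < 1e-3

    def test_gap_fill_leave_one_out(self, maize_model):
        doys, vals = self._composites(maize_model)
        mid = len(doys) // 2
        series = phen.smooth_daily(np.delete(doys, mid), np.delete(vals, mid))
        assert abs(series(doys[mid]) - vals[mid]) < 0.05

    def test_too_few_composites_raises(self):
        with pytest.raises(QualityError):
            phen.smooth_daily(np.arange(5) * 8.0 + 100, np.zeros(5))

    def test_long_gap_raises(self, maize_model):
        doys, vals = self._composites(maize_model, drop=slice(8, 13))
        with pytest.raises(QualityError):
            phen.smooth_daily(doys, vals)

    def test_output_clipped(self):
        doys = np.arange(100.0, 300.0, 8.0)
        vals = np.where(doys % 16 < 8, 0.99, 0.97)
        series = phen.smooth_daily(doys, vals)
        assert series.values.max() <= 1.0


class TestBuildShapeModel:
    def test_mean_of_shifted_pair(self, clean_series):
        a = clean_series
        b = phen.WdrviSeries(1, 2000, a.grid.copy(), a.values + 0.2)
        model = phen.build_shape_model([a, b], (150, 200, 240, 265))
        np.testing.assert_allclose(model.curve, a.values + 0.1, atol=1e-12)

    def test_single_year_identity(self, clean_series):
        model = phen.build_shape_model([clean_series], (150, 200, 240, 265))
        np.testing.assert_array_equal(model.curve, clean_series.values)

    def test_mismatched_grids_raise(self, clean_series):
        other = phen.WdrviSeries(1, 2000, clean_series.grid[:-10],
                                 clean_series.values[:-10])
        with pytest.raises(InputError):
            phen.build_shape_model([clean_series, other], (150, 200, 240, 265))


class TestFitShapeModel:
    def test_identity(self, maize_model, clean_series):
        fit = phen.fit_shape_model(maize_model, clean_series)
        assert fit.converged
        assert fit.rmse < 1e-9
        assert (fit.xscale, fit.tshift, fit.yscale) == pytest.approx(
            (1.0, 0.0, 1.0), abs=1e-6
        )

    def test_pure_shift(self, maize_model):
        # series(x) = h(x - 10): observed season 10 days late
        grid = maize_model.grid
        shifted = np.interp(grid - 10, grid, maize_model.curve)
        series = phen.WdrviSeries(0, 2000, grid.copy(), shifted)
        fit = phen.fit_shape_model(maize_model, series)
        assert fit.xscale == pytest.approx(1.0, abs=0.02)
        assert fit.tshift == pytest.approx(-10.0, abs=0.5)

    def test_amplitude_scaling(self, maize_model, clean_series):
        series = phen.WdrviSeries(0, 2000, clean_series.grid.copy(),
                                  0.9 * clean_series.values)
        fit = phen.fit_shape_model(maize_model, series)
        assert fit.yscale == pytest.approx(0.9, abs=0.01)
        assert fit.rmse < 1e-6

    def test_shift_equivariance_of_detected_dates(self, maize_model):
        grid = maize_model.grid
        for k in (-10.0, 7.0, 15.0):
            shifted = np.interp(grid - k, grid, maize_model.curve)
            series = phen.WdrviSeries(0, 2000, grid.copy(), shifted)
            fit = phen.fit_shape_model(maize_model, series)
            dates = phen.stage_dates_from_fit(fit, maize_model)
            for stage, ref in zip((1, 2), (200.0, 240.0)):
                assert dates[stage] == pytest.approx(ref + k, abs=0.5)


class TestStageDatesFromFit:
    @pytest.mark.parametrize("params, d0, expected", [
        ((1.0, 0.0, 1.0), 200, 200),
        ((1.0, -10.0, 1.0), 200, 210),
        ((1.25, 0.0, 1.0), 250, 200),
    ])
    def test_linear_map(self, maize_model, params, d0, expected):
        fit = phen.SmfFit(*params, rmse=0.0, converged=True, iterations=1)
        model = phen.ShapeModel(
            crop="maize", grid=np.arange(1.0, 367.0),
            curve=np.interp(np.arange(1.0, 367.0), maize_model.grid,
                            maize_model.curve),
            reference_dates=(150, d0 if d0 < 240 else 200,
                             d0 if d0 >= 240 else 240, 300),
        )
        doys = phen.stage_dates_from_fit(
            fit, model, stages=(1 if d0 < 240 else 2,)
        )
        assert list(doys.values())[0] == expected

    def test_unconverged_fit_rejected(self, maize_model):
        fit = phen.SmfFit(1.0, 0.0, 1.0, rmse=0.1, converged=False,
                          iterations=200)
        with pytest.raises(DetectionError):
            phen.stage_dates_from_fit(fit, maize_model)


class TestThresholdCrossings:
    def test_constructed_crossing(self, maize_model):
        # shift the reference curve so the -0.68 upward crossing (at the
        # reference emergence date 150) lands at DOY 141.0
        grid = maize_model.grid
        series = phen.WdrviSeries(0, 2000, grid.copy(),
                                  np.interp(grid + 9, grid, maize_model.curve))
        up, down = phen.detect_threshold_crossings(
            series, -0.68, -0.68, peak_doy=maize_model.peak_doy - 9
        )
        assert up == 141
        assert down == 265 - 9

    def test_no_crossing_raises(self):
        grid = np.arange(100.0, 300.0)
        series = phen.WdrviSeries(0, 2000, grid, np.full(grid.shape, 0.2))
        with pytest.raises(DetectionError):
            phen.detect_threshold_crossings(series, -0.68, -0.68, 200.0)

    def test_exact_grid_point_crossing(self):
        grid = np.arange(140.0, 260.0)
        values = np.interp(grid, [140, 150, 200, 250, 260],
                           [-0.75, -0.68, 0.3, -0.7, -0.75])
        series = phen.WdrviSeries(0, 2000, grid, values)
        up, _ = phen.detect_threshold_crossings(series, -0.68, -0.68, 200.0)
        assert up == 150


class TestPixelSelection:
    @pytest.mark.parametrize("fraction, kept", [
        (0.85, True), (0.50, False), (0.80, True),
    ])
    def test_cutoff_inclusive(self, fraction, kept):
        cdl = pd.DataFrame({"pixel_id": [0], "year": [2000],
                            "crop_fraction": [fraction]})
        assert phen.select_crop_pixels(cdl).iloc[0] == kept

    def test_invalid_fraction_raises(self):
        cdl = pd.DataFrame({"pixel_id": [0], "year": [2000],
                            "crop_fraction": [1.2]})
        with pytest.raises(InputError):
            phen.select_crop_pixels(cdl)


class TestCountyAggregation:
    def test_mean_of_pixels(self):
        px = pd.DataFrame({
            "pixel_id": [0, 1], "county_id": [5, 5], "year": [2000, 2000],
            "s1": [150, 150], "s2": [200, 202], "s3": [240, 240],
            "s4": [265, 265],
        })
        records = phen.aggregate_to_county(px, "maize")
        assert records[0].stages == (150, 201, 240, 265)
        assert records[0].durations == (51, 39, 25)
        assert records[0].n_pixels == 2

    def test_single_pixel_passthrough(self):
        px = pd.DataFrame({
            "pixel_id": [0], "county_id": [1], "year": [2001],
            "s1": [151], "s2": [199], "s3": [241], "s4": [266],
        })
        records = phen.aggregate_to_county(px, "maize")
        assert records[0].stages == (151, 199, 241, 266)

    def test_empty_input_yields_no_records(self):
        px = pd.DataFrame(columns=["pixel_id", "county_id", "year",
                                   "s1", "s2", "s3", "s4"])
        assert phen.aggregate_to_county(px, "maize") == []


class TestCprInterpolation:
    def test_symmetric_ratios(self):
        t50 = phen.interpolate_cpr([180, 187, 194, 201], [0, 25, 75, 100])
        assert t50 in (190, 191)  # logistic midpoint 190.5 +- 0.5

    def test_exact_fifty_at_center(self):
        t50 = phen.interpolate_cpr([183, 190, 197], [10, 50, 90])
        assert t50 == 190

    def test_never_straddles_raises(self):
        with pytest.raises(InputError):
            phen.interpolate_cpr([180, 187, 194], [5, 10, 20])


class TestEvaluateRmse:
    def test_identical_vectors(self):
        assert phen.evaluate_rmse([1, 2, 3], [1, 2, 3]) == 0.0

    def test_constant_offset(self):
        assert phen.evaluate_rmse([153, 203, 243], [150, 200, 240]) == \
            pytest.approx(3.0)

    def test_symmetric_errors(self):
        assert phen.evaluate_rmse([3, -3], [0, 0]) == pytest.approx(3.0)

    def test_empty_raises(self):
        with pytest.raises(InputError):
            phen.evaluate_rmse([], [])


class TestPipelineRecovery:
    def test_stage_order_invariant_and_truth_recovery(self, small_bundle,
                                                      small_config,
                                                      maize_model):
        pixel_stages, report = phen.detect_stages(
            small_bundle.reflectance, small_bundle.cdl, maize_model,
            small_config.crop,
        )
        assert report["detected"] > 0.8 * report["n_pixel_years"]
        s = pixel_stages[["s1", "s2", "s3", "s4"]].to_numpy()
        assert (np.diff(s, axis=1) > 0).all()
        merged = pixel_stages.merge(
            small_bundle.truth.pixel_stages,
            on=["pixel_id", "county_id", "year"], suffixes=("_det", "_true"),
        )
        for k in range(1, 5):
            rmse = phen.evaluate_rmse(merged[f"s{k}_det"],
                                      merged[f"s{k}_true"])
            assert rmse <= 5.0
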