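"""Calibration fits, mean-method aggregation and rod quantification."""

import math

import numpy as np
import pytest

from spectralcal import calibration as cal
from spectralcal.calibration import RoiMeasurement
from spectralcal.datasets import example_calibration_records
from spectralcal.errors import InconsistentGroupError, InsufficientDataError
from spectralcal.phantom import default_truth, synthetic_measurements

CONCS = [0.5, 1.0, 2.0, 5.0, 10.0, 15.0]


def make_measurements(le_of_c, he_of_c, concs=CONCS, **meta):
    defaults = dict(material="iodine", kv="120", dose_pct=100.0, fat_ring=False)
    defaults.update(meta)
    return [
        RoiMeasurement(le_mean=le_of_c(c), he_mean=he_of_c(c), concentration=c, **defaults)
        for c in concs
    ]


class TestBaseIntercepts:
    def test_noiseless_lines_recover_intercepts(self):
        ms = make_measurements(lambda c: 26.0 * c - 5.0, lambda c: 10.0 * c + 0.7)
        le_base, he_base, delta = cal.fit_base_intercepts(ms)
        assert math.isclose(le_base, -5.0, abs_tol=1e-9)
        assert math.isclose(he_base, 0.7, abs_tol=1e-9)
        assert math.isclose(delta, 5.7, abs_tol=1e-9)

    def test_all_zero_input(self):
        ms = make_measurements(lambda c: 0.0, lambda c: 0.0)
        assert cal.fit_base_intercepts(ms) == (0.0, 0.0, 0.0)

    def test_single_concentration_rejected(self):
        ms = make_measurements(lambda c: c, lambda c: c, concs=[5.0, 5.0])
        with pytest.raises(InsufficientDataError):
            cal.fit_base_intercepts(ms)

    def test_monte_carlo_recovery_unbiased(self):
        # Gaussian sigma = 2 HU on both channels, 200 replicates
        truth = default_truth("iodine", "120")
        rng = np.random.default_rng(2024)
        deltas = []
        for _ in range(200):
            ms = synthetic_measurements(
                truth, CONCS, "iodine", "120", noise_sd=(2.0, 2.0), rng=rng
            )
            deltas.append(cal.fit_base_intercepts(ms)[2])
        assert abs(np.mean(deltas) - truth.delta_base) < 0.5


class TestDerFit:
    def test_exact_material_line(self):
        ms = make_measurements(lambda c: 2.5 * (10.0 * c) + 3.0, lambda c: 10.0 * c)
        assert math.isclose(cal.fit_der(ms), 2.5, abs_tol=1e-9)

    def test_water_line_yields_slope_one(self):
        ms = make_measurements(lambda c: 10.0 * c, lambda c: 10.0 * c)
        assert math.isclose(cal.fit_der(ms), 1.0, abs_tol=1e-9)

    def test_constant_he_rejected(self):
        ms = make_measurements(lambda c: 10.0 * c, lambda c: 5.0)
        with pytest.raises(InsufficientDataError):
            cal.fit_der(ms)

    def test_monte_carlo_recovery(self):
        truth = default_truth("iodine", "120")
        rng = np.random.default_rng(99)
        ders = [
            cal.fit_der(
                synthetic_measurements(
                    truth, CONCS, "iodine", "120", noise_sd=(2.0, 2.0), rng=rng
                )
            )
            for _ in range(200)
        ]
        assert abs(np.mean(ders) - truth.true_der) < 0.05


class TestAlphaFit:
    def test_noiseless_slope_recovered(self):
        truth = default_truth("iodine", "120")
        ms = synthetic_measurements(truth, CONCS, "iodine", "120")
        alpha = cal.fit_alpha(ms, truth.true_der, 0.5, truth.delta_base)
        assert math.isclose(alpha, truth.implied_alpha(0.5), rel_tol=1e-9)

    def test_zero_cm_gives_zero_alpha(self):
        ms = make_measurements(lambda c: 7.0, lambda c: 7.0)  # LE = HE everywhere
        assert math.isclose(cal.fit_alpha(ms, 2.0, 0.5, 0.0), 0.0, abs_tol=1e-12)

    def test_w_rescales_alpha_by_blend_ratio(self):
        truth = default_truth("iron", "140")
        ms = synthetic_measurements(truth, [2.0, 5.0, 15.0, 25.0], "iron", "140")
        der, delta = truth.true_der, truth.delta_base
        a_half = cal.fit_alpha(ms, der, 0.5, delta)
        a_one = cal.fit_alpha(ms, der, 1.0, delta)
        assert math.isclose(a_one / a_half, der / (0.5 * der + 0.5), rel_tol=1e-9)


class TestCalibrateConfiguration:
    def test_noiseless_roundtrip(self):
        truth = default_truth("iodine", "140")
        ms = synthetic_measurements(truth, CONCS, "iodine", "140")
        rec = cal.calibrate_configuration(ms, w=0.5)
        assert math.isclose(rec.delta_base, truth.delta_base, rel_tol=1e-9)
        assert math.isclose(rec.der, truth.true_der, rel_tol=1e-9)
        assert math.isclose(rec.alpha, truth.implied_alpha(0.5), rel_tol=1e-9)
        assert rec.diagnostics["der"].r_squared == pytest.approx(1.0)

    def test_empty_input_rejected(self):
        with pytest.raises(InsufficientDataError):
            cal.calibrate_configuration([])

    def test_mixed_configurations_rejected(self):
        ms = synthetic_measurements(default_truth("iodine", "120"), CONCS, "iodine", "120")
        other = synthetic_measurements(default_truth("iodine", "140"), CONCS, "iodine", "140")
        with pytest.raises(InconsistentGroupError):
            cal.calibrate_configuration(ms + other)

    def test_calibrate_table_groups_by_configuration(self):
        ms = synthetic_measurements(default_truth("iodine", "120"), CONCS, "iodine", "120")
        other = synthetic_measurements(default_truth("iodine", "140"), CONCS, "iodine", "140")
        records = cal.calibrate_table(ms + other)
        assert {(r.material, r.kv) for r in records} == {("iodine", "120"), ("iodine", "140")}


class TestAggregation:
    def test_published_der_group_mean(self):
        frame = cal.records_to_frame(example_calibration_records())
        group = frame[(frame.material == "iodine") & (frame.kv == "140")]
        params = cal.aggregate_mean_method(cal.records_from_frame(group))
        assert round(params.der_avg, 2) == 2.49
        assert round(params.der_sd, 2) == 0.02

    def test_published_alpha_group_mean(self):
        frame = cal.records_to_frame(example_calibration_records())
        group = frame[(frame.material == "iron") & (frame.kv == "120")]
        params = cal.aggregate_mean_method(cal.records_from_frame(group))
        assert round(params.alpha_avg, 2) == 4.06
        assert round(params.alpha_sd, 2) == 0.04

    def test_single_record_mean_equals_record_sd_zero(self):
        rec = example_calibration_records()[0]
        params = cal.aggregate_mean_method([rec])
        assert params.der_avg == rec.der
        assert params.der_sd == 0.0
        assert params.n_configs == 1

    def test_mixed_kv_rejected(self):
        records = example_calibration_records()
        with pytest.raises(InconsistentGroupError):
            cal.aggregate_mean_method(records)  # spans materials and kVs

    def test_aggregate_table_produces_four_groups(self):
        params = cal.aggregate_table(example_calibration_records())
        assert len(params) == 4
        assert {(p.material, p.kv) for p in params} == {
            ("iodine", "120"), ("iodine", "140"), ("iron", "120"), ("iron", "140"),
        }


class TestQuantify:
    def _calibrated(self, material="iodine", kv="120", w=0.5):
        truth = default_truth(material, kv)
        concs = CONCS if material == "iodine" else [2.0, 5.0, 15.0, 25.0]
        ms = synthetic_measurements(truth, concs, material, kv)
        rec = cal.calibrate_configuration(ms, w=w)
        return truth, ms, cal.aggregate_mean_method([rec])

    def test_exact_model_gives_zero_error(self):
        _, ms, params = self._calibrated()
        out = cal.quantify_with_mean_method(ms, params)
        assert np.allclose(out["error_corrected_pct"], 0.0, atol=1e-9)
        assert np.allclose(out["concentration_corrected"], out["concentration_mg_ml"])

    def test_correction_beats_uncorrected_under_base_mismatch(self):
        _, ms, params = self._calibrated()
        out = cal.quantify_with_mean_method(ms, params)
        # delta_base = -5 HU injected by the generator is the only bias source
        assert (
            out["error_corrected_pct"].abs() <= out["error_uncorrected_pct"].abs()
        ).all()
        assert out["error_uncorrected_pct"].abs().max() > 1.0

    def test_zero_concentration_rod_quantified_but_excluded_from_errors(self):
        truth, _, params = self._calibrated()
        blank = synthetic_measurements(truth, [0.0, 5.0], "iodine", "120")
        out = cal.quantify_with_mean_method(blank, params)
        assert np.isnan(out.loc[0, "error_corrected_pct"])
        assert math.isclose(out.loc[0, "concentration_corrected"], 0.0, abs_tol=1e-9)
        assert not np.isnan(out.loc[1, "error_corrected_pct"])


class TestSerialization:
    def test_records_roundtrip(self, tmp_path):
        truth = default_truth("iron", "120")
        ms = synthetic_measurements(truth, [2.0, 5.0, 15.0, 25.0], "iron", "120")
        records = [cal.calibrate_configuration(ms)]
        path = tmp_path / "records.json"
        cal.save_records(records, path)
        assert cal.load_records(path) == records

    def test_params_roundtrip(self, tmp_path):
        params = cal.aggregate_table(example_calibration_records())
        path = tmp_path / "params.json"
        cal.save_params(params, path)
        assert cal.load_params(path) == params

    def test_roi_table_roundtrip(self, tmp_path):
        ms = synthetic_measurements(
            default_truth("iodine", "120"), CONCS, "iodine", "120"
        )
        path = tmp_path / "roi.csv"
        cal.write_roi_table(ms, path)
        assert cal.read_roi_table(path) == ms
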