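"""Spirometry and mechanics: onset detection, FEV/FVC, calibration,
multistroke IC, and PV compliance."""

import numpy as np
import pytest

from ferretlung import pft, synthetic
from ferretlung.errors import InputError, NoExhalationError, CalibrationError
from ferretlung.types import FlowVolumeTrace, PVLoop, ManeuverSegment


def _trace_from_flow(t, flow):
    dt = t[1] - t[0]
    volume = np.cumsum(flow) * dt
    return FlowVolumeTrace(time_s=t, flow_ml_s=flow, volume_ml=volume)


class TestOnsetDetection:
    def test_step_onset_within_one_sample(self):
        t = np.arange(0, 3, 0.001)
        flow = np.where(t >= 1.0, 150 * np.exp(-(t - 1.0) / 0.2), 0.0)
        trace = _trace_from_flow(t, flow)
        assert pft.detect_exhalation_start(trace) == pytest.approx(1.0, abs=0.001)

    def test_ramp_back_extrapolates_to_ramp_start(self):
        t = np.arange(0, 2, 0.001)
        flow = np.clip((t - 0.5) * 100, 0, None)  # ramp from 0.5 s
        trace = _trace_from_flow(t, flow)
        assert pft.detect_exhalation_start(trace) == pytest.approx(0.5, abs=0.002)

    def test_all_zero_flow_raises(self):
        t = np.arange(0, 1, 0.001)
        trace = _trace_from_flow(t, np.zeros_like(t))
        with pytest.raises(NoExhalationError):
            pft.detect_exhalation_start(trace)


class TestSpirometry:
    def test_mono_exponential_closed_form(self, mono_trace):
        preset, trace = mono_trace
        res = pft.compute_spirometry(trace, x_seconds=0.4)
        assert res.fev_ml == pytest.approx(30 * (1 - np.exp(-2)), rel=1e-3)
        assert res.ratio == pytest.approx(1 - np.exp(-2), rel=1e-3)
        assert not res.truncated

    def test_bi_exponential_obstructed(self):
        preset = synthetic.TracePreset(
            fvc_ml=30.0, fractions=(0.5, 0.5), taus_s=(0.1, 2.0),
            t_onset_s=0.1, duration_s=16.0,
        )
        trace = synthetic.make_expiration_trace(preset)
        res = pft.compute_spirometry(trace, x_seconds=0.4)
        expected = 0.5 * (1 - np.exp(-4)) + 0.5 * (1 - np.exp(-0.2))
        assert res.ratio == pytest.approx(expected, rel=1e-3)
        assert res.ratio < 0.7  # obstructed by the human COPD criterion

    def test_x_beyond_trace_saturates(self, mono_trace):
        _, trace = mono_trace
        res = pft.compute_spirometry(trace, x_seconds=100.0)
        assert res.fev_ml == pytest.approx(res.fvc_ml)
        assert res.ratio == 1.0

    def test_length_normalisation_cancels_in_ratio(self, mono_trace):
        _, trace = mono_trace
        res = pft.compute_spirometry(trace, x_seconds=0.4, body_length_cm=40.0)
        assert res.fev_per_cm == pytest.approx(res.fev_ml / 40.0)
        assert res.fev_per_cm / res.fvc_per_cm == pytest.approx(res.ratio)

    def test_invalid_x_rejected(self, mono_trace):
        _, trace = mono_trace
        with pytest.raises(InputError):
            pft.compute_spirometry(trace, x_seconds=0.0)


class TestCalibration:
    def test_five_controls_yield_0p3(self, control_traces):
        # analytic crossing of 1 - exp(-x/0.2) > 0.7 is at x = 0.2408 s
        res = pft.calibrate_fev_x(control_traces)
        assert res.x_star_s == pytest.approx(0.3)

    def test_strict_inequality_rule_raises_with_table(self):
        """The criterion is strictly '> floor': a ratio that only reaches the
        floor (here floor=1.0, the saturation limit) never satisfies it, and
        the error carries the full ratio table."""
        traces = [synthetic.make_expiration_trace(synthetic.TracePreset(seed=0))]
        with pytest.raises(CalibrationError) as err:
            pft.calibrate_fev_x(traces, floor=1.0)
        assert err.value.table is not None
        assert "stat" in err.value.table.columns

    def test_median_quantile_uses_third_lowest_of_five(self):
        # 3 healthy (tau 0.2, crossing 0.24 s) + 2 obstructed (tau 0.5,
        # crossing 0.60 s): the median tracks the healthy majority
        healthy = [
            synthetic.make_expiration_trace(
                synthetic.TracePreset(taus_s=(0.2,), duration_s=16.0, seed=i)
            )
            for i in range(3)
        ]
        obstructed = [
            synthetic.make_expiration_trace(
                synthetic.TracePreset(taus_s=(0.5,), duration_s=16.0, seed=i)
            )
            for i in range(2)
        ]
        res = pft.calibrate_fev_x(healthy + obstructed, quantile="median")
        assert res.x_star_s == pytest.approx(0.3)
        # requiring all five defers x* to the obstructed crossing
        res_min = pft.calibrate_fev_x(healthy + obstructed, quantile="min")
        assert res_min.x_star_s == pytest.approx(0.7)

    def test_floor_monotonicity(self, control_traces):
        # lowering the floor can only lower (or keep) the calibrated x*
        xs = [
            pft.calibrate_fev_x(control_traces, floor=f).x_star_s
            for f in (0.3, 0.5, 0.7)
        ]
        assert xs == sorted(xs)


class TestMultistrokeIC:
    def test_linear_lung_equals_single_stroke(self):
        # compliance 2 mL/cmH2O: strokes of 24 and 30 mL sum to the 3->30 stroke
        ic = pft.ic_multistroke(
            ManeuverSegment(3, 15, 24.0), ManeuverSegment(15, 30, 30.0)
        )
        assert ic == pytest.approx(54.0)

    def test_state_function_for_monotone_pv(self):
        pv = lambda p: synthetic.salazar_knowles_volume(p, 60, 55, 0.1)
        s1, s2 = synthetic.make_multistroke_segments(pv, delta=0.0)
        assert pft.ic_multistroke(s1, s2) == pytest.approx(pv(30) - pv(3), rel=1e-12)

    def test_recruitment_correction_inverts_generator(self):
        pv = lambda p: synthetic.salazar_knowles_volume(p, 60, 55, 0.1)
        s1, s2 = synthetic.make_multistroke_segments(pv, delta=0.05)
        truth = pv(30) - pv(3)
        assert pft.ic_multistroke(s1, s2, correction_delta=0.05) == pytest.approx(truth)
        assert pft.ic_multistroke(s1, s2) == pytest.approx(1.05 * truth)

    def test_non_abutting_segments_rejected(self):
        with pytest.raises(InputError):
            pft.ic_multistroke(
                ManeuverSegment(3, 15, 24.0), ManeuverSegment(14, 30, 30.0)
            )


class TestPVCompliance:
    def test_exact_recovery_noise_free(self):
        loop = synthetic.make_pv_loop(60, 55, 0.1)
        fit = pft.fit_pv_compliance(loop, p_ref_cmh2o=5.0)
        assert fit.a_ml == pytest.approx(60, rel=1e-6)
        assert fit.b_ml == pytest.approx(55, rel=1e-6)
        assert fit.k_per_cmh2o == pytest.approx(0.1, rel=1e-6)
        assert fit.cst_ml_cmh2o == pytest.approx(55 * 0.1 * np.exp(-0.5), rel=1e-6)
        assert fit.accepted and not fit.linear_fallback

    def test_heavy_noise_fails_gate(self):
        loop = synthetic.make_pv_loop(60, 55, 0.1, noise_sd_ml=10.0, seed=3)
        fit = pft.fit_pv_compliance(loop)
        assert fit.r_squared <= 0.9
        assert not fit.accepted

    def test_linear_data_falls_back(self):
        p = np.linspace(3, 30, 10)
        loop = PVLoop(p, 5 + 2 * p, np.array(["deflation"] * 10))
        fit = pft.fit_pv_compliance(loop)
        assert fit.linear_fallback
        assert fit.cst_ml_cmh2o == pytest.approx(2.0)
        assert fit.accepted  # perfect linear fit

    def test_cst_decreasing_in_reference_pressure(self):
        loop = synthetic.make_pv_loop(60, 55, 0.1)
        csts = [pft.fit_pv_compliance(loop, p_ref_cmh2o=p).cst_ml_cmh2o for p in (3, 5, 10)]
        assert csts == sorted(csts, reverse=True)

    def test_too_few_points_rejected(self):
        loop = PVLoop([3, 10, 30], [10, 30, 50], ["deflation"] * 3)
        with pytest.raises(InputError):
            pft.fit_pv_compliance(loop)


class TestNormalizeByLength:
    def test_basic_and_errors(self):
        assert pft.normalize_by_length(40.0, 40.0) == 1.0
        with pytest.raises(InputError):
            pft.normalize_by_length(40.0, 0.0)
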