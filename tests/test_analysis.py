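"""Offline analysis: traces, ΔF/F, oracle re-detection, cycle stats, maps, error rates."""

import numpy as np
import pytest

from optoloop import (
    CameraConfig,
    DetectorConfig,
    Frame,
    LoadModel,
    PixelRect,
    RoiTrace,
    TissueParams,
    activation_map,
    cycle_stats,
    dff,
    extract_trace,
    fit_conduction_velocity,
    il_error_rate,
    make_circular_mask,
    offline_detect,
    predict_period,
    rtl_error_rate,
    run_session,
)


def _uniform_frames(values, shape=(128, 128)):
    return [
        Frame(pixels=np.full(shape, v, dtype=np.uint16),
              camera_timestamp_us=i * 2000, frame_index=i)
        for i, v in enumerate(values)
    ]


ROI = PixelRect(9, 62, 1, 4)


class TestTraceAndDff:
    def test_identical_frames_give_a_constant_trace(self):
        trace = extract_trace(_uniform_frames([1000] * 5), ROI)
        assert np.all(trace.values == 1000.0)

    def test_single_frame_trace(self):
        trace = extract_trace(_uniform_frames([777]), ROI)
        assert trace.values.tolist() == [777.0]

    def test_empty_stack_is_an_error(self):
        with pytest.raises(ValueError):
            extract_trace([], ROI)

    def test_constant_trace_has_zero_dff(self):
        trace = extract_trace(_uniform_frames([1000] * 6), ROI)
        assert np.all(dff(trace, (0, 3)) == 0.0)

    def test_four_percent_drop(self):
        trace = extract_trace(_uniform_frames([10000, 10000, 9600]), ROI)
        assert dff(trace, (0, 2))[-1] == pytest.approx(0.04)

    def test_empty_baseline_is_an_error(self):
        trace = extract_trace(_uniform_frames([1000] * 3), ROI)
        with pytest.raises(ValueError):
            dff(trace, (0, 0))

    def test_noise_free_ap_peaks_exactly_at_sensitivity(self):
        tissue = TissueParams(noise_sigma_px=0.0)
        mask = make_circular_mask((5.0, 9.5), 1.0, tissue)
        res = run_session(tissue=tissue, camera=CameraConfig(exposure_us=2000),
                          duration_us=150_000, mode="free-run",
                          init_stim_time_us=10_000, init_stim_mask=mask)
        trace = extract_trace(res.frames, ROI)
        peak = dff(trace, (0, 5)).max()
        assert abs(peak - tissue.sensitivity) <= 1.0 / tissue.f0


class TestOfflineDetect:
    CFG = DetectorConfig(roi=ROI, th=0.01, buffer_len=10)

    def test_constant_trace_has_no_events(self):
        trace = extract_trace(_uniform_frames([1000] * 30), ROI)
        assert offline_detect(trace, self.CFG).size == 0

    def test_single_step_drop_fires_once_at_the_first_post_step_sample(self):
        trace = extract_trace(_uniform_frames([1000] * 10 + [980] * 5), ROI)
        events = offline_detect(trace, self.CFG, protocol_window_us=50_000)
        assert events.tolist() == [10 * 2000.0]

    def test_blanked_interval_suppresses_and_resets(self):
        # the drop falls inside the blanked window; after the window the buffer
        # restarts from the new level, so nothing fires
        values = [1000] * 10 + [980] * 10
        trace = extract_trace(_uniform_frames(values), ROI)
        blanked = [(19_000.0, 25_000.0)]
        events = offline_detect(trace, self.CFG, blanked=blanked)
        assert events.size == 0

    def test_matches_online_detection_on_a_zero_cost_run(
        self, detector, protocol
    ):
        res = run_session(tissue=TissueParams(), camera=CameraConfig(exposure_us=2000),
                          duration_us=2_000_000, mode="closed-loop",
                          detector=detector, protocol=protocol,
                          init_stim_time_us=100_000, seed=11)
        trace = extract_trace(res.frames, detector.roi)
        blanked = [(t, t + protocol.window_us) for t in res.log.detection_times]
        events = offline_detect(trace, detector, blanked=blanked)
        assert np.array_equal(events, res.log.detection_times)

    def test_trace_shows_one_deflection_per_stimulation(self, detector, protocol):
        tissue = TissueParams(noise_sigma_px=0.0)
        res = run_session(tissue=tissue, camera=CameraConfig(exposure_us=2000),
                          duration_us=2_000_000, mode="closed-loop",
                          detector=detector, protocol=protocol,
                          init_stim_time_us=100_000)
        trace = extract_trace(res.frames, detector.roi)
        drops = dff(trace, (0, 10)) > tissue.sensitivity / 2
        n_deflections = int(np.sum(np.diff(drops.astype(int)) == 1))
        assert n_deflections == len(res.log.stimulations)


class TestCycleStats:
    def test_perfectly_regular_events(self):
        st = cycle_stats([0.0, 100_000.0, 200_000.0])
        assert st.mean_period_us == 100_000.0
        assert st.sd_period_us == 0.0
        assert st.cv_period == 0.0

    def test_irregular_events_population_sd(self):
        st = cycle_stats([0.0, 90_000.0, 210_000.0])
        assert st.mean_period_us == 105_000.0
        assert st.sd_period_us == 15_000.0

    def test_fewer_than_three_events_is_no_rhythm(self):
        with pytest.raises(ValueError):
            cycle_stats([0.0, 1.0])


class TestPredictPeriod:
    def test_doubling_pre_delay_shifts_both_ends_by_pre_delay(self, quiet_params):
        mask = make_circular_mask((5.0, 9.5), 1.0, quiet_params)
        lo1, hi1 = predict_period(quiet_params, mask, ROI, 0.01, 200_000, 2000)
        lo2, hi2 = predict_period(quiet_params, mask, ROI, 0.01, 400_000, 2000)
        assert lo2 - lo1 == pytest.approx(200_000)
        assert hi2 - hi1 == pytest.approx(200_000)

    def test_bench_geometry_lands_near_216_to_220_ms(self, quiet_params):
        # ~8 mm apex-to-base travel at 0.5 mm/ms plus the 200 ms delay
        mask = make_circular_mask((5.0, 9.5), 1.0, quiet_params)
        lo, hi = predict_period(quiet_params, mask, ROI, 0.01, 200_000, 2000)
        assert 214_000 <= lo <= hi <= 221_000

    def test_measured_period_falls_in_the_interval(self, detector, protocol):
        tissue = TissueParams(noise_sigma_px=0.0)
        res = run_session(tissue=tissue, camera=CameraConfig(exposure_us=2000),
                          duration_us=3_000_000, mode="closed-loop",
                          detector=detector, protocol=protocol,
                          init_stim_time_us=100_000, keep_frames=False)
        st = cycle_stats(res.log.detection_times)
        lo, hi = predict_period(tissue, protocol.mask, detector.roi, detector.th,
                                protocol.pre_delay_us, 2000)
        assert lo <= st.mean_period_us <= hi


class TestErrorRates:
    def test_no_loss_is_zero(self, quiet_params):
        res = run_session(tissue=quiet_params, camera=CameraConfig(exposure_us=2000),
                          duration_us=200_000, mode="free-run", keep_frames=False)
        assert il_error_rate(res.log) == 0.0

    def test_rates_recomputable_from_the_per_frame_csv(self, tmp_path, detector, protocol):
        res = run_session(tissue=TissueParams(noise_sigma_px=0.0),
                          camera=CameraConfig(exposure_us=1000),
                          duration_us=1_000_000, mode="closed-loop",
                          detector=detector, protocol=protocol,
                          load=LoadModel(il_cost_us=600.0, rtl_cost_us=1500.0,
                                         il_jitter_us=900.0),
                          seed=3, keep_frames=False)
        res.log.to_csv(tmp_path)
        import pandas as pd

        df = pd.read_csv(tmp_path / "frames.csv")
        produced = len(df)
        lost = int((df.status == "lost").sum())
        busy = int((df.status == "rtl-busy").sum())
        window = int((df.status == "protocol-window").sum())
        assert il_error_rate(res.log) == lost / produced
        assert rtl_error_rate(res.log) == busy / (produced - lost - window)
        assert 0.0 <= il_error_rate(res.log) <= 1.0
        assert 0.0 <= rtl_error_rate(res.log) <= 1.0

    def test_rtl_rate_needs_the_rtl_enabled(self, quiet_params):
        res = run_session(tissue=quiet_params, camera=CameraConfig(),
                          duration_us=100_000, mode="free-run", keep_frames=False)
        with pytest.raises(ValueError):
            rtl_error_rate(res.log)

    def test_double_speed_rtl_cost_misses_half(self, quiet_params, detector, protocol):
        res = run_session(tissue=quiet_params, camera=CameraConfig(exposure_us=1000),
                          duration_us=2_000_000, mode="closed-loop",
                          detector=detector, protocol=protocol,
                          load=LoadModel(rtl_cost_us=2000.0), keep_frames=False)
        assert rtl_error_rate(res.log) == pytest.approx(0.5, abs=0.01)


class TestActivationMap:
    def test_quiescent_stack_is_all_absent(self, quiet_params):
        res = run_session(tissue=quiet_params, camera=CameraConfig(exposure_us=2000),
                          duration_us=20_000, mode="free-run")
        amap = activation_map(res.frames, quiet_params)
        assert np.all(np.isnan(amap))

    def test_single_wave_matches_tissue_ground_truth(self):
        from optoloop import TissueState, advance_to, apply_stimulus

        tissue = TissueParams(noise_sigma_px=0.0)
        mask = make_circular_mask((5.0, 9.5), 1.0, tissue)
        res = run_session(tissue=tissue, camera=CameraConfig(exposure_us=1000),
                          duration_us=40_000, mode="free-run",
                          init_stim_time_us=2_000, init_stim_mask=mask)
        amap = activation_map(res.frames, tissue)
        # ground truth from the tissue model itself
        state = TissueState.quiescent(tissue)
        apply_stimulus(state, mask, 2_000.0, tissue)
        advance_to(state, 40_000.0, tissue)
        ok = np.isfinite(amap)
        assert ok.all()
        err = np.abs(amap[ok] - state.last_activation[ok])
        assert np.percentile(err, 95) <= 1500.0  # within ~one frame interval

    def test_regression_recovers_conduction_velocity(self):
        tissue = TissueParams(noise_sigma_px=0.0, cv_mm_ms=0.5)
        mask = make_circular_mask((5.0, 9.5), 1.0, tissue)
        res = run_session(tissue=tissue, camera=CameraConfig(exposure_us=1000),
                          duration_us=40_000, mode="free-run",
                          init_stim_time_us=2_000, init_stim_mask=mask)
        amap = activation_map(res.frames, tissue)
        cv = fit_conduction_velocity(amap, (5.0, 9.5), tissue)
        assert cv == pytest.approx(0.5, rel=0.05)


class TestRoiTraceInvariants:
    def test_times_must_be_strictly_increasing(self):
        with pytest.raises(ValueError):
            RoiTrace(times_us=np.array([0, 0, 1]), values=np.array([1.0, 1.0, 1.0]),
                     roi=ROI)

    def test_length_mismatch_is_an_error(self):
        with pytest.raises(ValueError):
            RoiTrace(times_us=np.array([0, 1]), values=np.array([1.0]), roi=ROI)
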