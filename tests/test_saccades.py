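"""Saccade detection, statistics, regression and stroke-phase analysis."""

import numpy as np
import pandas as pd
import pytest

from gazeflight import saccades
from gazeflight.saccades import (
    amplitude_duration_regression,
    detect_saccades,
    intersaccade_statistics,
    saccade_statistics,
    saccadic_fraction,
    stroke_phase_of_saccades,
)

from conftest import brute_force_runs, yaw_from_omega

FS = 2000.0


def _raised_cosine_omega(n, start, duration, peak, fs=FS):
    t = np.arange(n) / fs
    u = (t - start) / duration
    omega = np.zeros(n)
    inside = (u >= 0) & (u <= 1)
    omega[inside] = peak / 2.0 * (1 - np.cos(2 * np.pi * u[inside]))
    return omega


class TestDetectSaccades:
    def test_constant_yaw_no_events(self):
        yaw = yaw_from_omega(np.zeros(500))
        assert detect_saccades(yaw) == []

    def test_short_supra_threshold_burst_rejected(self):
        """1000 deg/s for only 10 ms fails the 12 ms duration rule."""
        omega = np.zeros(500)
        omega[100:120] = 1000.0  # 20 samples = 10 ms
        assert detect_saccades(yaw_from_omega(omega)) == []

    def test_threshold_is_strict(self):
        omega = np.zeros(500)
        omega[100:160] = 400.0  # equality never counts
        assert detect_saccades(yaw_from_omega(omega)) == []
        omega[100:160] = 400.0 + 1e-9
        assert len(detect_saccades(yaw_from_omega(omega))) == 1

    def test_raised_cosine_event_boundaries_match_brute_force(self):
        omega = _raised_cosine_omega(800, start=0.1, duration=0.024, peak=1500.0)
        yaw = yaw_from_omega(omega)
        events = detect_saccades(yaw)
        runs = brute_force_runs(omega, FS)
        assert len(events) == len(runs) == 1
        s, e = runs[0]
        assert events[0].thresh_start == pytest.approx(s / FS)
        assert events[0].thresh_end == pytest.approx((e - 1) / FS)

    def test_detector_equals_oracle_on_random_traces(self):
        """Run-length detector == independent brute-force scan, including
        boundary indices, over many random band-limited traces."""
        rng = np.random.default_rng(42)
        for _ in range(100):
            raw = rng.normal(0, 1, 400)
            kernel = np.hanning(21)
            omega = np.convolve(raw, kernel / kernel.sum(), mode="same") * 3000.0
            yaw = yaw_from_omega(omega)
            events = detect_saccades(yaw)
            runs = brute_force_runs(omega, FS)
            assert len(events) == len(runs)
            for ev, (s, e) in zip(events, runs):
                assert ev.thresh_start == pytest.approx(s / FS)
                assert ev.thresh_end == pytest.approx((e - 1) / FS)

    def test_count_monotone_in_threshold_and_duration(self):
        rng = np.random.default_rng(7)
        raw = rng.normal(0, 1, 4000)
        kernel = np.hanning(31)
        omega = np.convolve(raw, kernel / kernel.sum(), mode="same") * 4000.0
        yaw = yaw_from_omega(omega)
        counts = [len(detect_saccades(yaw, omega_threshold=th))
                  for th in np.arange(200.0, 801.0, 100.0)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))
        counts = [len(detect_saccades(yaw, min_duration_ms=ms))
                  for ms in np.arange(4.0, 41.0, 4.0)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_separate_runs_stay_separate_events(self):
        omega = np.zeros(1000)
        omega[100:140] = 900.0
        omega[142:182] = -900.0  # any sub-threshold gap splits events
        events = detect_saccades(yaw_from_omega(omega))
        assert len(events) == 2
        assert events[0].direction == "left" and events[1].direction == "right"

    def test_nonuniform_sampling_rejected(self):
        yaw = yaw_from_omega(np.zeros(100))
        yaw.t[50:] += 0.01
        with pytest.raises(ValueError, match="uniform"):
            detect_saccades(yaw)

    def test_noisy_amplitude_recovery_within_ten_percent(self, pipeline16):
        """1.3 mm marker noise + default smoothing: amplitudes >= 15 deg
        recover within 10%."""
        checked = 0
        for item in pipeline16:
            detectable = [p for p in item["truth"].saccades if p.detectable()]
            events = item["events"]
            assert len(events) == len(detectable)
            for ev, plan in zip(events, detectable):
                if abs(plan.amplitude) >= 15.0:
                    err = abs(abs(ev.amplitude_absolute) - abs(plan.amplitude))
                    assert err <= 0.10 * abs(plan.amplitude)
                    checked += 1
        assert checked > 30


class TestSaccadeStatistics:
    def _events(self, rows):
        return pd.DataFrame(rows)

    def test_single_event_summary_is_the_event(self):
        df = self._events([{
            "bird": "b0", "flight": "f0", "amplitude_absolute": -25.0,
            "amplitude_relative": -24.0, "duration_ms": 20.0,
            "peak_velocity": 1500.0, "mean_velocity": 1000.0,
        }])
        out = saccade_statistics(df, per="cohort")
        assert out["amplitude_absolute"].iloc[0] == 25.0  # magnitudes
        assert out["duration_ms"].iloc[0] == 20.0

    def test_cohort_averages_bird_medians_not_pooled(self):
        rows = []
        # bird A: many 20-deg saccades; bird B: one 40-deg saccade
        for k in range(9):
            rows.append({"bird": "A", "flight": f"f{k}", "amplitude_absolute": 20.0,
                         "amplitude_relative": 20.0, "duration_ms": 10.0,
                         "peak_velocity": 500.0, "mean_velocity": 450.0})
        rows.append({"bird": "B", "flight": "g0", "amplitude_absolute": 40.0,
                     "amplitude_relative": 40.0, "duration_ms": 30.0,
                     "peak_velocity": 900.0, "mean_velocity": 800.0})
        out = saccade_statistics(self._events(rows), per="cohort")
        assert out["amplitude_absolute"].iloc[0] == pytest.approx(30.0)  # not 20

    def test_recovered_median_close_to_generator(self, pipeline16):
        frames = [saccades.events_frame(item["events"], flight=item["rec"].trial_id,
                                        bird=item["rec"].bird_id)
                  for item in pipeline16]
        events = pd.concat(frames, ignore_index=True)
        true_amp = np.concatenate([
            [abs(p.amplitude) for p in item["truth"].saccades if p.detectable()]
            for item in pipeline16])
        out = saccade_statistics(events, per="cohort")
        assert out["amplitude_absolute"].iloc[0] == pytest.approx(
            np.median(true_amp), rel=0.15)


class TestIntersaccadeStatistics:
    def test_no_saccades_whole_trace_intersaccadic(self):
        yaw = yaw_from_omega(np.full(400, 50.0))
        out = intersaccade_statistics(yaw, [])
        assert out.loc[out.quantity == "omega_absolute", "n_samples"].iloc[0] == 400

    def test_stabilized_head_rotating_body(self):
        """Head still, body turning: relative rate ~ body rate, absolute ~ 0."""
        n = 1000
        yaw = yaw_from_omega(np.zeros(n))
        yaw.phi_body = -150.0 * yaw.t  # body turns at 150 deg/s
        yaw.phi_diff = yaw.phi_head - yaw.phi_body
        out = intersaccade_statistics(yaw, [])
        med = out.set_index("quantity")["median"]
        assert med["omega_absolute"] == pytest.approx(0.0, abs=1e-9)
        assert med["omega_relative"] == pytest.approx(150.0, rel=1e-6)

    def test_intersaccadic_slower_than_saccadic(self, pipeline16):
        for item in pipeline16[:4]:
            yaw, events = item["yaw"], item["events"]
            out = intersaccade_statistics(yaw, events)
            inter = out.set_index("quantity").loc["omega_absolute", "median"]
            sacc = np.median([ev.peak_velocity for ev in events])
            assert inter < sacc


class TestAmplitudeDurationRegression:
    def test_exact_line_recovered(self):
        x = np.array([10.0, 20.0, 30.0, 44.0])
        df = pd.DataFrame({"duration_ms": x, "amplitude_absolute": 1.5 * x - 14.0})
        fit = amplitude_duration_regression(df)
        assert fit["slope_deg_per_s"] == pytest.approx(1500.0)
        assert fit["intercept_deg"] == pytest.approx(-14.0)
        assert fit["r_squared"] == pytest.approx(1.0)

    def test_hand_computed_two_points_plus_midpoint(self):
        # (20 ms, 20 deg) and (40 ms, 50 deg): slope 1.5 deg/ms, intercept -10
        df = pd.DataFrame({"duration_ms": [20.0, 40.0, 30.0],
                           "amplitude_absolute": [20.0, 50.0, 35.0]})
        fit = amplitude_duration_regression(df)
        assert fit["slope_deg_per_s"] == pytest.approx(1500.0)
        assert fit["intercept_deg"] == pytest.approx(-10.0)

    def test_recovers_generator_regression(self, pipeline16):
        """Default schedules draw durations from the 1500 deg/s line, so the
        fitted slope lands near it (threshold-crossing durations are shorter
        than the full profile, biasing the slope slightly up)."""
        frames = [saccades.events_frame(item["events"]) for item in pipeline16]
        events = pd.concat(frames, ignore_index=True)
        fit = amplitude_duration_regression(events)
        assert fit["r_squared"] > 0.6  # boundary jitter under noise adds scatter
        assert fit["slope_deg_per_s"] == pytest.approx(1500.0, rel=0.25)

    def test_degenerate_durations_raise(self):
        df = pd.DataFrame({"duration_ms": [20.0] * 5,
                           "amplitude_absolute": np.arange(5.0)})
        with pytest.raises(ValueError, match="degenerate"):
            amplitude_duration_regression(df)


class TestSaccadicFraction:
    def test_constructed_trace_eighty_percent(self):
        """Three 40-deg saccades plus 30 deg of smooth drift over a 150-deg
        turn: saccades carry 120/150 = 80%."""
        fs, n = 2000.0, 3000
        t = np.arange(n) / fs
        phi = 30.0 * t / t[-1]  # smooth drift, 30 deg total
        events = []
        for k, start in enumerate((0.2, 0.6, 1.0)):
            u = np.clip((t - start) / 0.02, 0.0, 1.0)
            phi = phi + 40.0 * (u - np.sin(2 * np.pi * u) / (2 * np.pi))
        yaw = yaw_from_omega(np.zeros(n))
        yaw.phi_head = phi
        yaw.omega_head = np.gradient(phi, 1 / fs)
        events = saccades.detect_saccades(yaw)
        assert len(events) == 3
        percent, curve = saccadic_fraction(yaw, events, (0.0, t[-1]))
        assert percent == pytest.approx(80.0, abs=1.0)
        assert curve["cumulative_fraction"].iloc[-1] == pytest.approx(0.8, abs=0.01)

    def test_no_saccades_zero_percent(self):
        yaw = yaw_from_omega(np.full(1000, 100.0))  # sub-threshold drift
        percent, _ = saccadic_fraction(yaw, [], (0.0, yaw.t[-1]))
        assert percent == 0.0

    def test_zero_net_reorientation_flagged(self):
        yaw = yaw_from_omega(np.zeros(100))
        with pytest.raises(ValueError, match="zero net"):
            saccadic_fraction(yaw, [], (0.0, yaw.t[-1]))


class TestStrokePhase:
    @staticmethod
    def _beats():
        return pd.DataFrame([{"down_start": 0.0, "down_mid": 0.01, "down_end": 0.02,
                              "up_mid": 0.03, "up_end": 0.04}])

    def test_boundary_conventions(self):
        beats = {"f": self._beats()}
        events = pd.DataFrame([
            {"bird": "b", "flight": "f", "start": 0.0, "end": 0.01},
            {"bird": "b", "flight": "f", "start": 0.01, "end": 0.03},
        ])
        out = stroke_phase_of_saccades(events, beats)
        down_starts = out[(out.edge == "start") & (out.stroke == "down")]
        # one start exactly at down_start (0%), one at down_mid (50%)
        assert down_starts.loc[down_starts.bin_left == 0.0, "density"].iloc[0] == 0.5
        assert down_starts.loc[down_starts.bin_left == 50.0, "density"].iloc[0] == 0.5

    def test_histograms_sum_to_one_per_stroke_pair(self, pipeline16):
        frames = [saccades.events_frame(item["events"], flight=item["rec"].trial_id,
                                        bird=item["rec"].bird_id)
                  for item in pipeline16]
        events = pd.concat(frames, ignore_index=True)
        beats = {item["rec"].trial_id: item["beats"] for item in pipeline16}
        out = stroke_phase_of_saccades(events, beats)
        for edge, grp in out.groupby("edge"):
            assert grp["density"].sum() == pytest.approx(1.0)

    def test_event_outside_beats_warned(self):
        events = pd.DataFrame([{"bird": "b", "flight": "f", "start": 9.0, "end": 9.1}])
        with pytest.warns(UserWarning, match="outside"):
            out = stroke_phase_of_saccades(events, {"f": self._beats()})
        assert out.empty
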