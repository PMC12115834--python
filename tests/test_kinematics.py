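"""Attack-kinematics pipeline: smoothing, differentiation, windows, angles."""

import io
import json
import math

import numpy as np
import pandas as pd
import pytest
from scipy.signal import butter, freqz

from loomstrike import (
    AttackGenParams,
    SmoothingParams,
    TrackedTrajectory,
    align_and_average,
    analyze_attack,
    angular_size_at_end,
    compute_speed_acceleration,
    detect_attack_window,
    elevation_azimuth,
    gen_attack,
    peak_metrics,
    read_digitized_points,
    smooth_positions,
)
from loomstrike import loom


def _csv(n=200, missing_label=None, nan_frames=()):
    cols = {"frame": np.arange(n)}
    for label in ("damselfly_head", "damselfly_tail", "fly_centroid"):
        if label == missing_label:
            continue
        for ax in "xyz":
            col = np.linspace(0, 10, n)
            cols[f"{label}_{ax}"] = col
    df = pd.DataFrame(cols)
    for f in nan_frames:
        for c in df.columns:
            if c.startswith("damselfly_head"):
                df.loc[f, c] = np.nan
    return io.StringIO(df.to_csv(index=False))


class TestReadDigitizedPoints:
    def test_roundtrip_length_and_span(self):
        traj = read_digitized_points(_csv(200), frame_rate=1000.0)
        assert traj.n_frames == 200
        assert traj.times[-1] == pytest.approx(0.199)

    def test_missing_label_is_format_error(self):
        with pytest.raises(ValueError, match="fly_centroid"):
            read_digitized_points(_csv(missing_label="fly_centroid"))

    def test_interior_nans_become_flagged_gaps(self):
        traj = read_digitized_points(_csv(nan_frames=(10, 11, 12, 50, 51)))
        assert traj.gaps["damselfly_head"].sum() == 5
        assert traj.gaps["fly_centroid"].sum() == 0

    def test_non_monotone_frames_rejected(self):
        df = pd.read_csv(_csv(50))
        df.loc[5, "frame"] = 100
        with pytest.raises(ValueError, match="increasing"):
            read_digitized_points(io.StringIO(df.to_csv(index=False)))

    def test_label_map_resolves_generic_headers(self):
        df = pd.read_csv(_csv(50))
        mapping = {}
        for i, label in enumerate(("damselfly_head", "damselfly_tail", "fly_centroid"), 1):
            for ax in "xyz":
                mapping[f"pt{i}_{ax.upper()}"] = f"{label}_{ax}"
        inverse = {v: k for k, v in mapping.items()}
        foreign = df.rename(columns=inverse)
        traj = read_digitized_points(io.StringIO(foreign.to_csv(index=False)), label_map=mapping)
        assert traj.n_frames == 50


class TestSmoothing:
    def test_constant_preserved(self):
        pos = np.full((100, 3), 7.5)
        out = smooth_positions(pos, 1000.0)
        assert np.allclose(out, 7.5, atol=1e-9)

    def test_linear_ramp_recovered_in_interior(self):
        t = np.arange(400) / 1000.0
        pos = np.column_stack([3.0 * t, -1.0 * t, 0.5 * t]) * 1000  # mm
        out = smooth_positions(pos, 1000.0)
        interior = slice(50, -50)
        # oracle: least-squares line fit on the interior
        for ax in range(3):
            coef = np.polyfit(t[interior], pos[interior, ax], 1)
            rel = np.abs(out[interior, ax] - np.polyval(coef, t[interior])) / (
                np.abs(pos[interior, ax]).max()
            )
            assert rel.max() < 1e-3

    def test_high_frequency_attenuated(self):
        # 100 Hz sinusoid under a 50 Hz cutoff: amplitude down by > 50%
        t = np.arange(1000) / 1000.0
        pos = np.column_stack([np.sin(2 * np.pi * 100 * t)] * 3)
        out = smooth_positions(pos, 1000.0, SmoothingParams(butterworth_cutoff=50.0))
        assert np.abs(out[100:-100, 0]).max() < 0.5
        # frequency-response oracle: |H(100 Hz)|^2 (forward-backward) is far below 0.5
        b, a = butter(2, 50.0, fs=1000.0)
        w, h = freqz(b, a, worN=[100.0], fs=1000.0)
        assert np.abs(h[0]) ** 2 < 0.1

    def test_short_series_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            smooth_positions(np.zeros((8, 3)), 1000.0, SmoothingParams(savgol_window=11))

    def test_long_gap_rejected(self):
        pos = np.ones((100, 3))
        pos[40:50] = np.nan
        with pytest.raises(ValueError, match="gap"):
            smooth_positions(pos, 1000.0)

    def test_savgol_window_validation(self):
        with pytest.raises(ValueError):
            SmoothingParams(savgol_window=10).validate(1000.0)
        with pytest.raises(ValueError):
            SmoothingParams(butterworth_cutoff=600.0).validate(1000.0)


class TestDifferentiation:
    def test_straight_line_exact(self):
        t = np.arange(300) / 1000.0
        pos = np.column_stack([200.0 * t, np.zeros_like(t), np.zeros_like(t)])  # 0.2 m/s
        speed, accel = compute_speed_acceleration(pos, 1000.0)
        assert np.abs(speed - 0.2).max() < 1e-9
        assert np.abs(accel).max() < 1e-6

    def test_stationary(self):
        pos = np.full((50, 3), 3.0)
        speed, accel = compute_speed_acceleration(pos, 1000.0)
        assert np.abs(speed).max() < 1e-12
        assert np.abs(accel).max() < 1e-12

    def test_constant_acceleration_closed_form(self):
        # from rest at 5 m/s^2 for 0.1 s -> 0.5 m/s
        t = np.arange(101) / 1000.0
        pos = np.column_stack([0.5 * 5.0 * t**2 * 1000.0, np.zeros_like(t), np.zeros_like(t)])
        speed, accel = compute_speed_acceleration(pos, 1000.0)
        assert speed[-1] == pytest.approx(0.5, rel=0.01)
        assert np.abs(accel[5:-5] - 5.0).max() < 0.05


class TestAttackWindow:
    def test_hover_then_dart_found_near_onset(self):
        params = AttackGenParams(
            profile="constant_speed",
            peak_speed=0.2,
            hover_duration=100.0,
            hover_jitter_sd=0.005,
            digitization_noise_sd=0.0,
        )
        traj, truth = gen_attack(params, 3)
        pos = smooth_positions(traj.points["damselfly_head"], traj.frame_rate)
        speed, _ = compute_speed_acceleration(pos, traj.frame_rate)
        start, end, fallback = detect_attack_window(
            speed, traj.frame_rate, traj.end_frame, hover_speed_threshold=0.1
        )
        assert not fallback
        assert abs(start - truth["dart_onset_frame"]) <= 5
        assert end == traj.end_frame

    def test_no_hover_falls_back_to_full_series(self):
        speed = np.full(200, 0.3)
        start, end, fallback = detect_attack_window(speed, 1000.0, 199)
        assert fallback and (start, end) == (0, 199)

    def test_all_stationary_flags_fallback_window(self):
        speed = np.zeros(200)
        start, end, fallback = detect_attack_window(speed, 1000.0, 199)
        assert fallback  # hover runs to the end: no dart exists


class TestAngles:
    n = 20

    def _fly(self):
        return np.zeros((self.n, 3))

    def test_wall_normal_axis(self):
        head = np.column_stack([np.linspace(30, 5, self.n), np.zeros(self.n), np.zeros(self.n)])
        _, _, me, ma = elevation_azimuth(head, self._fly())
        assert me == 0.0 and ma == 0.0

    def test_directly_above_is_undefined_azimuth(self):
        head = np.column_stack([np.zeros(self.n), np.zeros(self.n), np.linspace(30, 5, self.n)])
        elev, azim, me, ma = elevation_azimuth(head, self._fly())
        assert me == pytest.approx(90.0)
        assert np.isnan(azim).all() and math.isnan(ma)

    def test_behind_folds_to_180(self):
        head = np.column_stack([-np.linspace(30, 5, self.n), np.zeros(self.n), np.zeros(self.n)])
        _, _, _, ma = elevation_azimuth(head, self._fly())
        assert ma == pytest.approx(180.0)

    def test_lateral_folding_symmetry(self):
        left = np.column_stack([np.ones(self.n) * 5, np.ones(self.n) * 5, np.zeros(self.n)])
        right = left * np.array([1.0, -1.0, 1.0])
        assert elevation_azimuth(left, self._fly())[3] == pytest.approx(
            elevation_azimuth(right, self._fly())[3]
        )

    def test_coincident_points_flagged(self):
        head = self._fly().copy()
        head[5:] += 1.0
        elev, azim, _, _ = elevation_azimuth(head, self._fly(), reference="per_frame")
        assert np.isnan(elev[:5]).all()

    def test_rigid_motion_invariances(self, rng):
        params = AttackGenParams(approach_azimuth=30.0, approach_elevation=15.0)
        traj, _ = gen_attack(params, 11)
        base = analyze_attack(traj)
        # rigid translation leaves speed and acceleration unchanged
        shifted = TrackedTrajectory(
            frame_rate=traj.frame_rate,
            points={k: v + np.array([5.0, -3.0, 8.0]) for k, v in traj.points.items()},
            outcome=traj.outcome,
            end_frame=traj.end_frame,
        )
        moved = analyze_attack(shifted)
        assert np.allclose(moved.speed, base.speed, atol=1e-12)
        assert np.allclose(moved.acceleration, base.acceleration, atol=1e-9)
        # rigid rotation about Z leaves elevation unchanged
        th = np.radians(37.0)
        R = np.array(
            [[np.cos(th), -np.sin(th), 0.0], [np.sin(th), np.cos(th), 0.0], [0.0, 0.0, 1.0]]
        )
        rotated = TrackedTrajectory(
            frame_rate=traj.frame_rate,
            points={k: v @ R.T for k, v in traj.points.items()},
            outcome=traj.outcome,
            end_frame=traj.end_frame,
        )
        rot = analyze_attack(rotated)
        assert np.allclose(rot.elevation, base.elevation, atol=1e-9, equal_nan=True)


class TestPeakMetrics:
    def test_constant_speed_tie_breaks_to_last_frame(self):
        speed = np.full(100, 0.25)
        accel = np.zeros(100)
        t_ms = np.arange(100) - 99.0
        pk, pa, tp = peak_metrics(speed, accel, t_ms, (10, 99))
        assert pk == 0.25 and tp == 0.0

    def test_monotone_speed_peaks_at_window_end(self):
        speed = np.linspace(0, 0.4, 100)
        t_ms = np.arange(100) - 99.0
        _, _, tp = peak_metrics(speed, np.gradient(speed), t_ms, (0, 99))
        assert tp == 0.0

    def test_programmed_peak_recovered(self):
        params = AttackGenParams(
            profile="accelerating", peak_speed=0.3, peak_time_before_contact=25.0, end_distance=1.5
        )
        traj, truth = gen_attack(params, 4)
        k = analyze_attack(traj)
        assert k.peak_speed == pytest.approx(truth["peak_speed"], rel=0.03)
        assert abs(k.time_of_peak_speed - truth["time_of_peak_speed_ms"]) <= 3.0


class TestAngularSize:
    def test_head_width_twice_distance_gives_90(self):
        assert angular_size_at_end(1.0, 2.0) == pytest.approx(90.0)

    def test_far_limit(self):
        assert angular_size_at_end(1e6, 2.2) < 1e-3

    def test_derived_value_and_cross_module_consistency(self):
        # 2.2 mm head at 3 mm -> ~40 degrees, same law as the looming model
        assert angular_size_at_end(3.0, 2.2) == pytest.approx(40.3, abs=0.05)
        stim = loom.LoomStimulus(r_over_v=1.1, theta_onset=1.0, theta_max=179.0)
        assert angular_size_at_end(3.0, 2.2) == pytest.approx(
            loom.angular_size(stim, 3.0), rel=1e-12
        )

    def test_contact_is_domain_error(self):
        with pytest.raises(ValueError):
            angular_size_at_end(0.0, 2.2)


class TestAlignAndAverage:
    def _kin(self, speed, seed=0):
        params = AttackGenParams(peak_speed=speed, digitization_noise_sd=0.0, hover_jitter_sd=0.0)
        traj, _ = gen_attack(params, seed)
        return analyze_attack(traj)

    def test_identical_series_mean_equals_series(self):
        k = self._kin(0.2)
        out = align_and_average([k, k], "speed")
        assert np.allclose(out["mean"], k.speed)
        assert np.allclose(out["sd"].fillna(0.0), 0.0)
        assert (out["n"] == 2).all()

    def test_n_steps_down_where_short_series_starts(self):
        slow = self._kin(0.1)  # longer event
        fast = self._kin(0.3)  # shorter event
        out = align_and_average([slow, fast], "speed")
        assert out["n"].iloc[0] == 1
        assert out["n"].iloc[-1] == 2
        assert set(out["n"]) == {1, 2}

    def test_monte_carlo_mean_near_truth(self):
        kins = [
            analyze_attack(
                gen_attack(AttackGenParams(profile="constant_speed", peak_speed=0.2), s)[0]
            )
            for s in range(50)
        ]
        out = align_and_average(kins, "speed")
        # mid-approach timepoints where all events overlap
        full = out[out["n"] == 50]
        mid = full[(full["t_ms"] > -150) & (full["t_ms"] < -50)]
        se = (mid["sd"] / np.sqrt(mid["n"])).to_numpy()
        assert (np.abs(mid["mean"] - 0.2) < 2 * se + 0.002).all()

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            align_and_average([], "speed")
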