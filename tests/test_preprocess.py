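import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import posturekit as pk
from posturekit.errors import CalibrationError, MissingSensorError, PostureKitError
from posturekit.preprocess import lowpass, rotation_to_vertical
from posturekit.records import SensorRecording
from posturekit.synthetic import MountModel, PostureSpec, DayProtocol, simulate_day

SENSORS = ("waist", "thigh", "ankle")


def rodrigues_reference(axis, angle):
    """Term-by-term Rodrigues expansion, independent of the implementation."""
    ux, uy, uz = axis
    c, s = np.cos(angle), np.sin(angle)
    return np.array(
        [
            [c + ux**2 * (1 - c), ux * uy * (1 - c) - uz * s, ux * uz * (1 - c) + uy * s],
            [uy * ux * (1 - c) + uz * s, c + uy**2 * (1 - c), uy * uz * (1 - c) - ux * s],
            [uz * ux * (1 - c) - uy * s, uz * uy * (1 - c) + ux * s, c + uz**2 * (1 - c)],
        ]
    )


def _recording_from_vector(v, n=100, fs=50.0):
    return SensorRecording(
        sample_rate=fs,
        time=np.arange(n) / fs,
        data={"thigh": np.tile(np.asarray(v, float), (n, 1))},
    )


class TestRotationToVertical:
    def test_already_aligned_gives_identity(self):
        assert np.allclose(rotation_to_vertical([0, 0, 1]), np.eye(3), atol=1e-12)

    def test_x_axis_input_maps_to_z(self):
        R = rotation_to_vertical([1, 0, 0])
        assert np.allclose(R @ [1, 0, 0], [0, 0, 1], atol=1e-12)

    def test_thirty_degree_tilt_matches_explicit_rodrigues_expansion(self):
        v = np.array([0.0, np.sin(np.radians(30)), np.cos(np.radians(30))])
        R = rotation_to_vertical(v)
        # axis = cross(v, z) normalised; angle = angle(v, z) = 30 deg
        axis = np.cross(v, [0, 0, 1.0])
        axis /= np.linalg.norm(axis)
        expected = rodrigues_reference(axis, np.radians(30))
        assert np.allclose(R, expected, atol=1e-12)
        assert np.allclose(R @ v, [0, 0, 1], atol=1e-12)

    def test_antiparallel_uses_pi_about_x_convention(self):
        R = rotation_to_vertical([0, 0, -1])
        assert np.allclose(R, np.diag([1.0, -1.0, -1.0]), atol=1e-12)
        assert np.allclose(R @ [0, 0, -1], [0, 0, 1], atol=1e-12)

    def test_near_zero_magnitude_is_a_labelled_failure(self):
        with pytest.raises(CalibrationError):
            rotation_to_vertical([0.0, 0.0, 0.0])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(-1, 1), min_size=3, max_size=3))
    def test_random_vectors_map_onto_plus_z(self, v):
        v = np.asarray(v)
        if np.linalg.norm(v) < 1e-3:
            return
        R = rotation_to_vertical(v)
        assert np.allclose(R.T @ R, np.eye(3), atol=1e-9)
        assert np.isclose(np.linalg.det(R), 1.0, atol=1e-9)
        mapped = R @ (v / np.linalg.norm(v))
        assert np.allclose(mapped, [0, 0, 1], atol=1e-9)


class TestAlignment:
    def test_estimate_requires_a_long_enough_interval_inside_recording(self):
        rec = _recording_from_vector([0, 0, 1])
        with pytest.raises(CalibrationError):
            pk.estimate_alignment(rec, (0.0, 0.5))
        with pytest.raises(CalibrationError):
            pk.estimate_alignment(rec, (10.0, 12.0))

    def test_apply_requires_every_sensor(self):
        rec = _recording_from_vector([0, 0, 1])
        with pytest.raises(MissingSensorError):
            pk.apply_alignment(rec, {})

    def test_standing_day_aligns_to_pure_gravity_for_any_mount(self):
        postures = {"standing": PostureSpec("standing", {s: 0.0 for s in SENSORS}, jitter_sd=0.0)}
        mount = MountModel(
            {s: r for s, r in zip(SENSORS, [
                rodrigues_reference(np.array([1.0, 0, 0]), 0.7),
                rodrigues_reference(np.array([0, 1.0, 0]), -1.2),
                rodrigues_reference(np.array([0.6, 0.8, 0]), 2.0),
            ])},
            wobble_sd=0.0,
        )
        rec, track = simulate_day(
            DayProtocol((("standing", 5.0),)), postures=postures, mount=mount, noise_sd=0.0
        )
        rots = pk.estimate_alignment(rec, (0.0, 5.0))
        aligned = pk.apply_alignment(rec, rots)
        for s in SENSORS:
            assert np.allclose(aligned.data[s], [0, 0, 1], atol=1e-9)

    def test_alignment_preserves_norms_and_is_idempotent(self, small_benchmark):
        day = small_benchmark[0]
        iv = day.annotations.first("standing")
        rots = pk.estimate_alignment(day.recording, (iv.start_s, iv.end_s))
        aligned = pk.apply_alignment(day.recording, rots)
        for s in SENSORS:
            assert np.allclose(
                np.linalg.norm(aligned.data[s], axis=1),
                np.linalg.norm(day.recording.data[s], axis=1),
                atol=1e-12,
            )
        again = pk.estimate_alignment(aligned, (iv.start_s, iv.end_s))
        for s in SENSORS:
            assert np.allclose(again[s].matrix, np.eye(3), atol=1e-9)


class TestLowpass:
    def test_dc_gain_is_unity(self):
        rec = _recording_from_vector([0.3, -0.2, 0.9], n=500)
        out = lowpass(rec)
        assert np.allclose(out.data["thigh"], rec.data["thigh"], atol=1e-9)

    @pytest.mark.parametrize("freq", [1.0, 2.0])
    def test_attenuation_matches_analytic_butterworth_squared_magnitude(self, freq):
        fs, fc, n = 50.0, 3.0, 3000
        t = np.arange(n) / fs
        x = np.sin(2 * np.pi * freq * t)
        rec = SensorRecording(fs, t, {"thigh": np.column_stack([x, x, x])})
        y = lowpass(rec, cutoff_hz=fc).data["thigh"][:, 0]
        mid = slice(n // 4, 3 * n // 4)
        design = np.column_stack([np.sin(2 * np.pi * freq * t[mid]), np.cos(2 * np.pi * freq * t[mid])])
        coef, *_ = np.linalg.lstsq(design, y[mid], rcond=None)
        measured = np.hypot(*coef)
        analytic = 1.0 / (1.0 + (freq / fc) ** 4)  # |H|^2 of 2nd-order Butterworth
        assert measured == pytest.approx(analytic, rel=0.01)

    @pytest.mark.parametrize("freq", [4.0, 8.0, 12.0])
    def test_attenuation_matches_prewarped_digital_response(self, freq):
        # the bilinear-transform design follows the analog curve in
        # tan-prewarped frequency; this holds right up towards Nyquist
        fs, fc, n = 50.0, 3.0, 6000
        t = np.arange(n) / fs
        x = np.sin(2 * np.pi * freq * t)
        rec = SensorRecording(fs, t, {"thigh": np.column_stack([x, x, x])})
        y = lowpass(rec, cutoff_hz=fc).data["thigh"][:, 0]
        mid = slice(n // 4, 3 * n // 4)
        design = np.column_stack([np.sin(2 * np.pi * freq * t[mid]), np.cos(2 * np.pi * freq * t[mid])])
        coef, *_ = np.linalg.lstsq(design, y[mid], rcond=None)
        measured = np.hypot(*coef)
        warped = np.tan(np.pi * freq / fs) / np.tan(np.pi * fc / fs)
        expected = 1.0 / (1.0 + warped**4)
        assert measured == pytest.approx(expected, rel=0.005, abs=1e-9)

    def test_centred_impulse_response_is_symmetric(self):
        n = 1001
        x = np.zeros(n)
        x[n // 2] = 1.0
        rec = SensorRecording(50.0, np.arange(n) / 50.0, {"thigh": np.column_stack([x, x, x])})
        y = lowpass(rec).data["thigh"][:, 0]
        assert np.allclose(y, y[::-1], atol=1e-12)

    def test_short_segment_is_a_labelled_failure(self):
        rec = _recording_from_vector([0, 0, 1], n=20)
        with pytest.raises(PostureKitError):
            lowpass(rec)

    def test_filtering_commutes_with_alignment(self, small_benchmark):
        day = small_benchmark[0]
        iv = day.annotations.first("standing")
        rots = pk.estimate_alignment(day.recording, (iv.start_s, iv.end_s))
        a_then_f = lowpass(pk.apply_alignment(day.recording, rots))
        f_then_a = pk.apply_alignment(lowpass(day.recording), rots)
        for s in SENSORS:
            assert np.allclose(a_then_f.data[s], f_then_a.data[s], atol=1e-9)
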