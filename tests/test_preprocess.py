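"""Intensity-map construction, Green's interpolation, contact scoring."""

import numpy as np
import pytest

from egflow.geometry import BasketGeometry, GridLocation
from egflow.preprocess import (
    ContactReport,
    PixelGrid,
    PreprocessConfig,
    greens_interpolate,
    near_field_score,
    voltage_to_intensity,
)
from egflow.recording import EGMRecording
from egflow.synth import WaveScenario, simulate


class TestGreensInterpolation:
    def test_constant_field_reproduced_everywhere(self):
        out = greens_interpolate(np.full((8, 8), 3.7))
        np.testing.assert_allclose(out, 3.7)

    def test_values_reproduced_at_electrode_pixels(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(size=(8, 8))
        out = greens_interpolate(vals)
        grid = PixelGrid(BasketGeometry())
        for r in range(8):
            for c in range(8):
                pr, pc = grid.electrode_pixel(r, c)
                assert out[pr, pc] == pytest.approx(vals[r, c], abs=1e-6)

    def test_linearity(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=(2, 8, 8))
        a, b = 2.3, -0.7
        lhs = greens_interpolate(a * x + b * y)
        rhs = a * greens_interpolate(x) + b * greens_interpolate(y)
        np.testing.assert_allclose(lhs, rhs, atol=1e-8)

    def test_row_wrap_equivariance(self):
        """Circularly shifting input splines shifts the image circularly."""
        rng = np.random.default_rng(2)
        vals = rng.normal(size=(8, 8))
        shifted = np.roll(vals, 3, axis=0)
        out = greens_interpolate(vals)
        out_shifted = greens_interpolate(shifted)
        np.testing.assert_allclose(out_shifted, np.roll(out, 3 * 4, axis=0), atol=1e-8)

    def test_against_dense_linear_system_oracle(self):
        """Independent brute-force solve of the biharmonic kernel system,
        evaluated at random pixels."""
        rng = np.random.default_rng(3)
        vals = rng.normal(size=(8, 8))
        out = greens_interpolate(vals)

        def g(r):
            return 0.0 if r == 0 else r * r * (np.log(r) - 1.0)

        def dist(p, q):
            dr = abs(p[0] - q[0])
            dr = min(dr, 8 - dr)
            return np.hypot(dr, p[1] - q[1])

        nodes = [(r, c) for r in range(8) for c in range(8)]
        n = len(nodes)
        A = np.zeros((n + 1, n + 1))
        for i, p in enumerate(nodes):
            for j, q in enumerate(nodes):
                A[i, j] = g(dist(p, q))
            A[i, n] = 1.0
            A[n, i] = 1.0
        rhs = np.append(np.array([vals[r, c] for r, c in nodes]), 0.0)
        w = np.linalg.solve(A, rhs)
        for _ in range(20):
            pr, pc = rng.integers(0, 32), rng.integers(0, 29)
            p = (pr / 4.0, pc / 4.0)
            expected = sum(w[j] * g(dist(p, q)) for j, q in enumerate(nodes)) + w[n]
            assert out[pr, pc] == pytest.approx(expected, abs=1e-8)

    def test_bad_inputs(self):
        with pytest.raises(ValueError):
            greens_interpolate(np.zeros((7, 8)))
        bad = np.zeros((8, 8))
        bad[0, 0] = np.nan
        with pytest.raises(ValueError):
            greens_interpolate(bad)


class TestVoltageToIntensity:
    def test_two_second_segment_gives_105_frames(self, clean_focal_recording):
        rec, _ = clean_focal_recording
        stack = voltage_to_intensity(rec, 0.0)
        assert stack.n_frames == 105
        assert stack.frames.shape == (105, 32, 29)
        assert np.all((stack.frames >= 0) & (stack.frames <= 1))

    def test_intensity_scale_invariance_per_channel(self, clean_focal_recording):
        """Min-max normalization makes each channel's intensity invariant to
        positive rescaling of its raw voltage."""
        rec, _ = clean_focal_recording
        scaled = EGMRecording(
            signals=rec.signals * np.linspace(0.5, 8.0, 64)[:, None],
            sampling_rate=rec.sampling_rate,
            channel_labels=rec.channel_labels,
            ventricular_times=rec.ventricular_times,
        )
        a = voltage_to_intensity(rec, 0.0)
        b = voltage_to_intensity(scaled, 0.0)
        np.testing.assert_allclose(a.frames, b.frames, atol=1e-9)

    def test_propagating_wave_brightness_follows_activation_order(self):
        """The frame-wise intensity maximum traverses the grid from the
        origin outward, matching the simulator's activation times."""
        scn = WaveScenario(
            kind="planar_sr",
            origin=GridLocation(4, 0),
            conduction_velocity=15.0,
            cycle_length_ms=2000.0,
            noise_sd=0.0,
            qrst_amplitude_mv=0.0,
            seed=0,
        )
        rec, _ = simulate(scn, duration=4.0)
        stack = voltage_to_intensity(rec, 0.0)
        cols = []
        for k in range(0, 30):
            frame = stack.frames[k]
            if frame.max() > 0.5:
                cols.append(np.unravel_index(frame.argmax(), frame.shape)[1])
        assert len(cols) >= 5
        assert cols[0] <= 4  # starts near the origin column
        diffs = np.diff(cols)
        assert (diffs >= 0).mean() > 0.8  # argmax marches outward

    def test_segment_out_of_range(self, clean_focal_recording):
        rec, _ = clean_focal_recording
        with pytest.raises(ValueError, match="exceeds"):
            voltage_to_intensity(rec, 3.5)

    def test_flat_channel_stays_zero(self):
        rng = np.random.default_rng(0)
        sig = rng.normal(0, 0.3, size=(64, 4000))
        sig[10] = 0.0
        rec = EGMRecording(sig, 1000.0, BasketGeometry().channel_labels)
        from egflow.preprocess import _intensity_traces

        traces = _intensity_traces(rec, PreprocessConfig())
        assert np.all(traces[10] == 0.0)


class TestNearFieldScore:
    @staticmethod
    def _recording(atrial_p2p, vent_p2p, fs=1000.0, dur=8.0):
        """Channels with controllable atrial and ventricular amplitudes on
        disjoint supports."""
        n = int(dur * fs)
        t = np.arange(n) / fs
        vent_times = np.arange(0.5, dur - 0.5, 1.0)
        sig = np.zeros((64, n))
        # unit-p2p square wave: chunk peak-to-peak is exact, unlike a sampled sine
        atrial = 0.5 * np.sign(np.sin(2 * np.pi * 7 * t) + 1e-12)
        v_mask = np.zeros(n, dtype=bool)
        for tv in vent_times:
            a, b = int((tv - 0.05) * fs), int((tv + 0.25) * fs)
            v_mask[a:b] = True
        for ch in range(64):
            sig[ch] = np.where(v_mask, 0.0, atrial * atrial_p2p[ch])
            for tv in vent_times:
                a = int((tv + 0.05) * fs)
                sig[ch, a] = vent_p2p[ch] / 2.0
                sig[ch, a + 10] = -vent_p2p[ch] / 2.0
        return EGMRecording(
            sig, fs, BasketGeometry().channel_labels, ventricular_times=vent_times
        )

    def test_ratio_point_seven_is_not_flagged(self):
        """Strict 'less than 0.7': a channel at exactly 0.7 stays unflagged."""
        atrial = np.full(64, 0.7)
        vent = np.full(64, 1.0)
        rec = self._recording(atrial, vent)
        report = near_field_score(rec)
        assert report.near_field_score["A1"] == pytest.approx(0.7, abs=0.02)
        assert "A1" not in report.low_contact_flags

    def test_zero_atrial_component_flagged(self):
        atrial = np.full(64, 1.0)
        atrial[5] = 0.0
        rec = self._recording(atrial, np.full(64, 1.0))
        report = near_field_score(rec)
        lab = rec.channel_labels[5]
        assert report.near_field_score[lab] == pytest.approx(0.0, abs=1e-6)
        assert lab in report.low_contact_flags

    def test_synthetic_attenuated_channel_flagged_sibling_not(self):
        scn = WaveScenario(
            kind="fibrillatory", low_contact_channels=(("C4", 0.1),), seed=4
        )
        rec, _ = simulate(scn, duration=20.0)
        report = near_field_score(rec)
        assert "C4" in report.low_contact_flags
        assert "C5" not in report.low_contact_flags
        assert report.near_field_score["C4"] < report.near_field_score["C5"]

    def test_no_ventricular_events_is_error(self):
        rec = EGMRecording(
            np.random.default_rng(0).normal(size=(64, 2000)),
            1000.0,
            BasketGeometry().channel_labels,
        )
        with pytest.raises(ValueError, match="ventricular"):
            near_field_score(rec)

    def test_zero_ventricular_amplitude_scores_inf_unflagged(self):
        atrial = np.full(64, 1.0)
        vent = np.full(64, 1.0)
        vent[3] = 0.0
        rec = self._recording(atrial, vent)
        with pytest.warns(UserWarning, match="zero ventricular"):
            report = near_field_score(rec)
        lab = rec.channel_labels[3]
        assert np.isinf(report.near_field_score[lab])
        assert lab not in report.low_contact_flags
        assert ContactReport.LOW_CONTACT_THRESHOLD == 0.7
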