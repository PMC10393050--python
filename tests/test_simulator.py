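import numpy as np
import pandas as pd
import pytest
from scipy.signal import periodogram

from specklesense.exceptions import InvalidParameterError, NyquistError
from specklesense.simulator import (
    MotionModel,
    SimulationProtocol,
    generate_fixture_dataset,
    read_video,
    simulate_recording,
    simulate_speckle_field,
    write_video,
)


class TestSpeckleField:
    def test_deterministic_for_fixed_seed(self):
        a = simulate_speckle_field(64, 4, seed=11)
        b = simulate_speckle_field(64, 4, seed=11)
        np.testing.assert_array_equal(a, b)

    def test_fully_developed_contrast_near_unity(self):
        # fully developed speckle: std/mean of intensity ~ 1
        contrasts = [
            simulate_speckle_field(256, 4, seed=s).std() for s in range(8)
        ]  # unit mean by construction
        assert np.mean(contrasts) == pytest.approx(1.0, abs=0.1)

    def test_independent_seeds_are_uncorrelated(self):
        from specklesense.tracking import cross_correlate

        a = simulate_speckle_field(128, 4, seed=1)
        b = simulate_speckle_field(128, 4, seed=2)
        assert np.abs(cross_correlate(a, b)).max() < 0.2

    def test_parameter_validation(self):
        with pytest.raises(InvalidParameterError):
            simulate_speckle_field(64, 0.5, seed=0)
        with pytest.raises(InvalidParameterError):
            simulate_speckle_field(64, 64, seed=0)


class TestRecording:
    def test_static_scene_when_all_motion_disabled(self, quiet_motion):
        protocol = SimulationProtocol(
            frame_size=32, fps=500, frames_per_video=10, seed=1
        )
        video = simulate_recording(protocol, quiet_motion)
        for frame in video.frames[1:]:
            np.testing.assert_allclose(frame, video.frames[0], rtol=1e-6)

    def test_shape_and_reproducibility(self, short_protocol):
        motion = MotionModel()
        a = simulate_recording(short_protocol, motion, master_field_seed=5)
        b = simulate_recording(short_protocol, motion, master_field_seed=5)
        assert a.frames.shape == (short_protocol.n_frames, 64, 64)
        np.testing.assert_array_equal(a.frames, b.frames)
        np.testing.assert_array_equal(a.positions, b.positions)

    def test_field_on_truth_spectrum_peaks_at_drive_frequency(self, short_protocol):
        video = simulate_recording(short_protocol, MotionModel())
        freqs, pxx = periodogram(
            np.diff(video.positions[:, 0]), fs=short_protocol.fps
        )
        assert freqs[np.argmax(pxx)] == pytest.approx(
            short_protocol.drive_frequency, abs=1.0
        )

    def test_field_off_has_no_drive_line(self, short_protocol):
        from dataclasses import replace

        protocol = replace(short_protocol, field_on=False)
        video = simulate_recording(protocol, MotionModel())
        freqs, pxx = periodogram(np.diff(video.positions[:, 0]), fs=protocol.fps)
        drive_bin = np.argmin(np.abs(freqs - protocol.drive_frequency))
        off_band = pxx[(freqs > 20) & (np.abs(freqs - protocol.drive_frequency) > 10)]
        assert pxx[drive_bin] < 5.0 * np.median(off_band) + 1e-30

    def test_injected_amplitude_monotone_in_glucose(self):
        from dataclasses import replace

        amps = []
        base = SimulationProtocol(frame_size=32, fps=500, duration=0.5, seed=3)
        for level in (86.0, 105.0, 137.0, 198.0):
            video = simulate_recording(
                replace(base, glucose_level=level),
                MotionModel(pulse_amplitude=0, drift_step=0, noise_std=0),
            )
            spectrum = np.abs(np.fft.rfft(video.positions[:, 0]))
            amps.append(spectrum.max())
        assert np.all(np.diff(amps) > 0)

    def test_nyquist_violation_rejected(self):
        with pytest.raises(NyquistError):
            SimulationProtocol(fps=200.0, drive_frequency=140.0)


class TestFixtureDataset:
    def _template(self):
        return SimulationProtocol(frame_size=16, fps=50, duration=0.2,
                                  drive_frequency=10.0, seed=0)

    def test_row_count_13_levels_5_replicates(self, tmp_path):
        manifest = generate_fixture_dataset(
            self._template(), list(range(86, 99)), 5, tmp_path, dry_run=True
        )
        assert len(manifest) == 2 * 13 * 5
        assert manifest["field_on"].sum() == 13 * 5
        assert (~manifest["field_on"]).sum() == 13 * 5

    def test_minimal_dataset_round_trip(self, tmp_path):
        manifest = generate_fixture_dataset(
            self._template(), [100.0], 1, tmp_path, seed=4
        )
        assert len(manifest) == 2
        for row in manifest.itertuples():
            assert (tmp_path / row.path).exists()
        loaded = read_video(tmp_path / manifest["path"][0], self._template())
        assert loaded.frames.shape[0] == self._template().n_frames
        assert loaded.positions is not None

    def test_manifest_deterministic(self, tmp_path):
        a = generate_fixture_dataset(
            self._template(), [90.0, 120.0], 2, tmp_path / "a", seed=9, dry_run=True
        )
        b = generate_fixture_dataset(
            self._template(), [90.0, 120.0], 2, tmp_path / "b", seed=9, dry_run=True
        )
        pd.testing.assert_frame_equal(a, b)
        assert a.to_csv(index=False) == b.to_csv(index=False)

    def test_validation(self, tmp_path):
        with pytest.raises(InvalidParameterError):
            generate_fixture_dataset(self._template(), [], 1, tmp_path)
        with pytest.raises(InvalidParameterError):
            generate_fixture_dataset(self._template(), [100.0], 0, tmp_path)


def test_video_write_read_round_trip(tmp_path, short_protocol, quiet_motion):
    from dataclasses import replace

    protocol = replace(short_protocol, frames_per_video=5, frame_size=16)
    video = simulate_recording(protocol, quiet_motion)
    path = write_video(video, tmp_path / "v.tif")
    loaded = read_video(path, protocol)
    np.testing.assert_allclose(loaded.frames, video.frames, rtol=1e-6)
    np.testing.assert_allclose(loaded.positions, video.positions, atol=1e-12)
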