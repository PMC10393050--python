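import numpy as np
import pytest
from skimage.registration import phase_cross_correlation

from specklesense.exceptions import DegenerateInputError, InvalidInputError
from specklesense.simulator import (
    MotionModel,
    SimulationProtocol,
    simulate_recording,
    simulate_speckle_field,
)
from specklesense.tracking import (
    DisplacementSeries,
    cross_correlate,
    estimate_shift,
    track_video,
)


def _fourier_shift(image: np.ndarray, dx: float, dy: float) -> np.ndarray:
    f = np.fft.fftfreq(image.shape[0])
    fx, fy = np.meshgrid(f, f, indexing="xy")
    spectrum = np.fft.fft2(image) * np.exp(-2j * np.pi * (fx * dx + fy * dy))
    return np.fft.ifft2(spectrum).real


class TestCrossCorrelate:
    def test_autocorrelation_peaks_at_origin(self):
        frame = simulate_speckle_field(64, 4, seed=0)
        surface = cross_correlate(frame, frame)
        assert surface[0, 0] == pytest.approx(1.0, abs=1e-10)
        assert np.unravel_index(np.argmax(surface), surface.shape) == (0, 0)

    def test_circular_shift_moves_peak(self):
        frame = simulate_speckle_field(64, 4, seed=1)
        shifted = np.roll(frame, (3, -2), axis=(0, 1))  # dy=+3, dx=-2
        dx, dy, peak = estimate_shift(cross_correlate(frame, shifted))
        assert (dx, dy) == (-2.0, 3.0)
        assert peak == pytest.approx(1.0, abs=1e-10)

    def test_zero_lag_value_is_pearson_correlation(self):
        a = simulate_speckle_field(32, 3, seed=2)
        b = simulate_speckle_field(32, 3, seed=3)
        surface = cross_correlate(a, b)
        assert surface[0, 0] == pytest.approx(np.corrcoef(a.ravel(), b.ravel())[0, 1])

    def test_independent_fields_low_correlation(self):
        for seed in range(5):
            a = simulate_speckle_field(128, 4, seed=seed)
            b = simulate_speckle_field(128, 4, seed=seed + 100)
            assert np.abs(cross_correlate(a, b)).max() < 0.2

    def test_constant_frame_rejected(self):
        with pytest.raises(DegenerateInputError):
            cross_correlate(np.ones((8, 8)), np.random.default_rng(0).random((8, 8)))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(InvalidInputError):
            cross_correlate(np.zeros((8, 8)), np.zeros((8, 9)))


class TestEstimateShift:
    def test_delta_surface(self):
        surface = np.zeros((16, 16))
        surface[0, 0] = 1.0
        assert estimate_shift(surface) == (0.0, 0.0, 1.0)

    def test_integer_shift_exact_recovery(self):
        frame = simulate_speckle_field(64, 4, seed=5)
        for dy, dx in [(1, 0), (0, -4), (5, 7), (-3, 2)]:
            shifted = np.roll(frame, (dy, dx), axis=(0, 1))
            est_dx, est_dy, _ = estimate_shift(
                cross_correlate(frame, shifted), subpixel=False
            )
            assert (est_dx, est_dy) == (dx, dy)

    def test_subpixel_recovery_against_upsampled_oracle(self):
        # oracle: 16x-upsampled dense correlation (sign convention: the
        # registration shift is the negative of the pattern displacement)
        errors = []
        for seed in range(10):
            frame = simulate_speckle_field(64, 4, seed=seed)
            shifted = _fourier_shift(frame, 0.5, 0.0)
            dx, dy, _ = estimate_shift(cross_correlate(frame, shifted))
            (orow, ocol), _, _ = phase_cross_correlation(
                frame, shifted, upsample_factor=16
            )
            errors.append(np.hypot(dx - (-ocol), dy - (-orow)))
        assert max(errors) < 0.1

    def test_tie_break_prefers_smallest_lag(self):
        surface = np.zeros((8, 8))
        surface[0, 2] = surface[0, 0] = 0.5  # tie between lag (0,0) and (0,2)
        dx, dy, _ = estimate_shift(surface, subpixel=False)
        assert (dx, dy) == (0.0, 0.0)


class TestTrackVideo:
    def test_static_video_yields_zero_series(self, quiet_motion):
        protocol = SimulationProtocol(frame_size=32, fps=500, frames_per_video=6, seed=0)
        video = simulate_recording(protocol, quiet_motion)
        series = track_video(video)
        assert len(series) == 5
        np.testing.assert_allclose(series.dx, 0.0, atol=1e-9)
        np.testing.assert_allclose(series.dy, 0.0, atol=1e-9)
        np.testing.assert_allclose(series.peak, 1.0, atol=1e-9)

    def test_series_length_is_frames_minus_one(self):
        protocol = SimulationProtocol(
            frame_size=16, fps=500, frames_per_video=2501, seed=1
        )
        video = simulate_recording(
            protocol, MotionModel(drift_step=0, boiling_rate=0, noise_std=0)
        )
        assert len(track_video(video)) == 2500

    def test_noise_free_recovery_of_ground_truth(self, clean_drive_video):
        series = track_video(clean_drive_video)
        truth = clean_drive_video.pair_shifts
        rms = np.sqrt(
            np.mean((series.dx - truth[:, 0]) ** 2 + (series.dy - truth[:, 1]) ** 2)
        )
        assert rms < 0.05

    def test_shift_equivariance(self):
        # tracking a globally rolled copy gives identical sequential shifts
        protocol = SimulationProtocol(frame_size=32, fps=500, frames_per_video=8, seed=2)
        video = simulate_recording(
            protocol, MotionModel(noise_std=0, boiling_rate=0)
        )
        rolled = np.roll(video.frames, (5, -3), axis=(1, 2))
        a = track_video(video.frames)
        b = track_video(rolled)
        np.testing.assert_allclose(a.dx, b.dx, atol=1e-9)
        np.testing.assert_allclose(a.dy, b.dy, atol=1e-9)

    def test_sequential_cumsum_matches_fixed_reference(self, clean_drive_video):
        seq = track_video(clean_drive_video, mode="sequential")
        ref = track_video(clean_drive_video, mode="fixed_reference")
        np.testing.assert_allclose(np.cumsum(seq.dx), ref.dx, atol=0.1)

    def test_dominant_frequency_matches_drive(self, clean_drive_video):
        series = track_video(clean_drive_video)
        spectrum = np.abs(np.fft.rfft(series.dx))
        freqs = np.fft.rfftfreq(len(series), d=1.0 / series.fps)
        assert freqs[np.argmax(spectrum[1:]) + 1] == pytest.approx(
            clean_drive_video.protocol.drive_frequency, abs=1.0
        )

    def test_too_short_video_rejected(self):
        with pytest.raises(InvalidInputError):
            track_video(np.zeros((1, 8, 8)))
        with pytest.raises(InvalidInputError):
            track_video(np.random.default_rng(0).random((4, 8, 8)), mode="bogus")


def test_series_csv_round_trip(tmp_path, clean_drive_video):
    series = track_video(clean_drive_video)
    path = series.to_csv(tmp_path / "series.csv")
    loaded = DisplacementSeries.from_csv(path)
    np.testing.assert_allclose(loaded.dx, series.dx, atol=1e-9)
    np.testing.assert_allclose(loaded.peak, series.peak, atol=1e-9)
    assert loaded.fps == pytest.approx(series.fps)
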