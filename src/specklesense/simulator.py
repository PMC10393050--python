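"""Synthetic speckle-video generator.

Emulates the statistical structure the downstream analysis relies on:

* a fully developed secondary speckle pattern (circular complex-Gaussian
  field band-limited to a chosen grain size, intensity = squared magnitude,
  so the intensity histogram is negative-exponential with unit contrast);
* rigid sub-pixel translation of the pattern, the defocused-camera signature
  of skin-surface tilt. When the AC magnetic field is on, the magneto-optic
  rotation adds a sinusoidal tilt component at the drive frequency whose
  amplitude is linear in glucose concentration (Faraday rotation is linear
  in the glucose-attributable rotatory power);
* physiological confounds: a blood-pulse oscillation, a random-walk drift,
  and speckle "boiling" (gradual decorrelation of the pattern itself,
  modeled as per-frame convex mixing of the complex field with a fresh
  independent field);
* additive sensor noise and optional 8-bit quantization.

The acquisition protocol defaults mirror the bench setup: 128×128 px frames
at 500 FPS for 5 s (2501 frames), 150 Gauss AC field driven at 140 Hz.
Ground-truth injected displacement is stored alongside every video so the
tracking stage can be validated against it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

from .exceptions import InvalidParameterError, NyquistError

__all__ = [
    "SimulationProtocol",
    "MotionModel",
    "SpeckleVideo",
    "simulate_speckle_field",
    "simulate_recording",
    "generate_fixture_dataset",
    "write_video",
    "read_video",
]

#: Largest reference glucose level [mg/dl]; anchors the default gain so that
#: the strongest modulation stays in the sub-pixel regime (~0.5 px).
_MAX_REFERENCE_LEVEL = 198.0


@dataclass(frozen=True)
class SimulationProtocol:
    """Acquisition protocol of one recording.

    frames_per_video defaults to fps·duration + 1 (a recording spans the
    full duration inclusively, e.g. 2501 frames for 5 s at 500 FPS).
    """

    frame_size: int = 128
    fps: float = 500.0
    duration: float = 5.0
    frames_per_video: int | None = None
    drive_frequency: float = 140.0
    field_strength: float = 150.0
    field_on: bool = True
    glucose_level: float = 100.0
    seed: int = 0
    grain_size: float = 4.0
    quantize_8bit: bool = False

    def __post_init__(self) -> None:
        if self.fps <= 2.0 * self.drive_frequency:
            raise NyquistError(
                f"fps ({self.fps}) must exceed twice the drive frequency "
                f"({self.drive_frequency} Hz)"
            )
        if self.n_frames < 2:
            raise InvalidParameterError("frames_per_video must be >= 2")
        if self.glucose_level <= 0:
            raise InvalidParameterError("glucose_level must be > 0")
        if self.frame_size < 8:
            raise InvalidParameterError("frame_size must be >= 8")
        if not (1.0 <= self.grain_size < self.frame_size):
            raise InvalidParameterError("grain_size must be in [1, frame_size)")

    @property
    def n_frames(self) -> int:
        if self.frames_per_video is not None:
            return int(self.frames_per_video)
        return int(round(self.fps * self.duration)) + 1


@dataclass(frozen=True)
class MotionModel:
    """Displacement and degradation model of a recording.

    glucose_gain : speckle-shift amplitude per unit glucose [px/(mg/dl)].
        Default puts the largest reference level (198 mg/dl) at 0.5 px.
    pulse_frequency : blood-pulse rate [Hz] (~72 bpm).
    pulse_amplitude : pulse-induced shift amplitude [px].
    drift_step : per-frame random-walk standard deviation [px].
    boiling_rate : per-frame fraction of the complex field replaced by a
        fresh independent field; 0 disables boiling.
    noise_std : additive Gaussian intensity noise, as a fraction of the
        mean intensity.
    field_off_coupling : fraction of the glucose cue that leaks into the
        pulse waveform when the field is off (a weak, glucose-correlated
        second-harmonic perturbation), keeping field-off classification
        above chance but far below the lock-in condition.
    """

    glucose_gain: float = 0.5 / _MAX_REFERENCE_LEVEL
    pulse_frequency: float = 1.2
    pulse_amplitude: float = 0.1
    drift_step: float = 0.01
    boiling_rate: float = 0.02
    noise_std: float = 0.02
    field_off_coupling: float = 0.1

    def __post_init__(self) -> None:
        for name in (
            "glucose_gain",
            "pulse_frequency",
            "pulse_amplitude",
            "drift_step",
            "noise_std",
            "field_off_coupling",
        ):
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"{name} must be >= 0")
        if not (0.0 <= self.boiling_rate < 1.0):
            raise InvalidParameterError("boiling_rate must be in [0, 1)")


@dataclass
class SpeckleVideo:
    """Ordered stack of intensity frames plus acquisition metadata.

    positions holds the ground-truth absolute pattern displacement
    (dx, dy) of every frame relative to frame 0, in pixels.
    """

    frames: np.ndarray  # (n_frames, H, W), non-negative float32
    protocol: SimulationProtocol
    label: float
    positions: np.ndarray | None = None  # (n_frames, 2) -> (dx, dy)

    def __post_init__(self) -> None:
        if self.frames.ndim != 3:
            raise InvalidParameterError("frames must be a 3D stack")
        if np.any(self.frames < 0):
            raise InvalidParameterError("frame intensities must be >= 0")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def pair_shifts(self) -> np.ndarray:
        """Ground-truth (dx, dy) of each frame relative to its predecessor."""
        if self.positions is None:
            raise InvalidParameterError("video carries no ground-truth positions")
        return np.diff(self.positions, axis=0)


def _aperture_mask(grid_size: int, grain_size: float) -> np.ndarray:
    """Circular low-pass pupil whose cutoff sets the speckle grain size."""
    f = np.fft.fftfreq(grid_size)
    fx, fy = np.meshgrid(f, f, indexing="xy")
    radius = 1.0 / (2.0 * grain_size)
    return (fx * fx + fy * fy) <= radius * radius


def _fresh_pupil_field(
    mask: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Complex circular-Gaussian field on the pupil support, unit power."""
    n_active = int(mask.sum())
    values = rng.standard_normal(n_active) + 1j * rng.standard_normal(n_active)
    g = np.zeros(mask.shape, dtype=np.complex128)
    g[mask] = values / math.sqrt(2.0 * n_active)
    return g


def simulate_speckle_field(
    grid_size: int, grain_size: float, seed: int
) -> np.ndarray:
    """One fully developed speckle intensity pattern.

    A complex circular-Gaussian field is band-limited to the requested
    grain size; the returned intensity is its squared magnitude, normalized
    to unit mean. Deterministic for a fixed seed; the intensity histogram is
    approximately negative-exponential (contrast ≈ 1).
    """
    if grain_size < 1:
        raise InvalidParameterError("grain_size must be >= 1 px")
    if grain_size >= grid_size:
        raise InvalidParameterError("grain_size must be smaller than grid_size")
    rng = np.random.default_rng(seed)
    pupil = _fresh_pupil_field(_aperture_mask(grid_size, grain_size), rng)
    amp = np.fft.ifft2(pupil) * grid_size
    intensity = np.abs(amp) ** 2
    return intensity / intensity.mean()


def _phase_ramp(grid_size: int) -> tuple[np.ndarray, np.ndarray]:
    f = np.fft.fftfreq(grid_size)
    fx, fy = np.meshgrid(f, f, indexing="xy")
    return fx, fy


def _displacement_trajectory(
    protocol: SimulationProtocol, motion: MotionModel, rng: np.random.Generator
) -> np.ndarray:
    """Ground-truth absolute (dx, dy) positions, one row per frame."""
    n = protocol.n_frames
    t = np.arange(n) / protocol.fps
    dx = np.zeros(n)
    dy = np.zeros(n)

    cue = motion.glucose_gain * protocol.glucose_level
    if protocol.field_on:
        dx += cue * np.sin(2.0 * math.pi * protocol.drive_frequency * t)

    phase_x = rng.uniform(0.0, 2.0 * math.pi)
    phase_y = rng.uniform(0.0, 2.0 * math.pi)
    amp_jitter = 1.0 + 0.2 * rng.standard_normal()
    pulse = motion.pulse_amplitude * max(amp_jitter, 0.0)
    dx += pulse * np.sin(2.0 * math.pi * motion.pulse_frequency * t + phase_x)
    dy += pulse * np.sin(2.0 * math.pi * motion.pulse_frequency * t + phase_y)

    if not protocol.field_on and motion.field_off_coupling > 0:
        # Weak glucose-correlated distortion of the pulse waveform (second
        # harmonic); the only glucose cue available without the field.
        dx += (
            motion.field_off_coupling
            * cue
            * np.sin(2.0 * math.pi * 2.0 * motion.pulse_frequency * t + 2.0 * phase_x)
        )

    if motion.drift_step > 0:
        steps = rng.standard_normal((n, 2)) * motion.drift_step
        steps[0] = 0.0
        walk = np.cumsum(steps, axis=0)
        dx += walk[:, 0]
        dy += walk[:, 1]

    return np.column_stack([dx, dy])


def simulate_recording(
    protocol: SimulationProtocol,
    motion: MotionModel | None = None,
    master_field_seed: int | None = None,
) -> SpeckleVideo:
    """Render one speckle video under the given protocol and motion model.

    The pattern translation is applied as a Fourier phase ramp on the
    underlying complex field (exact sub-pixel, circular), boiling as convex
    mixing with fresh fields, and sensor noise in the intensity domain.
    Fully reproducible from (protocol.seed, master_field_seed).
    """
    if motion is None:
        motion = MotionModel()
    if master_field_seed is None:
        master_field_seed = protocol.seed + 1_000_003

    n = protocol.n_frames
    size = protocol.frame_size
    rng_motion = np.random.default_rng(protocol.seed)
    rng_field = np.random.default_rng(master_field_seed)

    positions = _displacement_trajectory(protocol, motion, rng_motion)

    mask = _aperture_mask(size, protocol.grain_size)
    fx, fy = _phase_ramp(size)
    pupil = _fresh_pupil_field(mask, rng_field)

    keep = math.sqrt(1.0 - motion.boiling_rate)
    mix = math.sqrt(motion.boiling_rate)

    frames = np.empty((n, size, size), dtype=np.float32)
    two_pi_j = -2.0j * math.pi
    for i in range(n):
        if i > 0 and motion.boiling_rate > 0:
            pupil = keep * pupil + mix * _fresh_pupil_field(mask, rng_field)
        ramp = np.exp(two_pi_j * (fx * positions[i, 0] + fy * positions[i, 1]))
        amp = np.fft.ifft2(pupil * ramp) * size
        intensity = np.abs(amp) ** 2
        mean = intensity.mean()
        if motion.noise_std > 0:
            intensity = intensity + (
                motion.noise_std * mean * rng_motion.standard_normal((size, size))
            )
        frames[i] = np.maximum(intensity, 0.0)

    if protocol.quantize_8bit:
        peak = frames.max()
        if peak > 0:
            frames = np.round(frames / peak * 255.0).astype(np.float32)

    return SpeckleVideo(
        frames=frames,
        protocol=protocol,
        label=protocol.glucose_level,
        positions=positions,
    )


def write_video(video: SpeckleVideo, path: str | Path) -> Path:
    """Write a video as a multi-page TIFF plus a ground-truth shift CSV."""
    path = Path(path)
    tifffile.imwrite(path, video.frames.astype(np.float32))
    if video.positions is not None:
        truth = pd.DataFrame(
            {
                "frame": np.arange(video.n_frames),
                "dx": video.positions[:, 0],
                "dy": video.positions[:, 1],
            }
        )
        truth.to_csv(path.with_suffix(".truth.csv"), index=False)
    return path


def read_video(
    path: str | Path,
    protocol: SimulationProtocol,
    label: float | None = None,
) -> SpeckleVideo:
    """Load a multi-page TIFF stack (and its shift CSV when present)."""
    path = Path(path)
    frames = np.asarray(tifffile.imread(path), dtype=np.float32)
    positions = None
    truth_path = path.with_suffix(".truth.csv")
    if truth_path.exists():
        truth = pd.read_csv(truth_path)
        positions = truth[["dx", "dy"]].to_numpy()
    return SpeckleVideo(
        frames=frames,
        protocol=protocol,
        label=protocol.glucose_level if label is None else label,
        positions=positions,
    )


def _child_seed(base_seed: int, index: int) -> int:
    """Deterministic per-video seed below 2**31."""
    ss = np.random.SeedSequence([int(base_seed), int(index)])
    return int(ss.generate_state(1)[0] % (2**31))


def iter_dataset_protocols(
    protocol_template: SimulationProtocol,
    reference_levels: Sequence[float],
    videos_per_level: int,
    seed: int,
):
    """Yield (protocol, replicate) for every (level, replicate, field) cell.

    Field-on and field-off variants of the same cell share the motion seed
    and the master field seed, isolating the effect of the drive field.
    """
    idx = 0
    for level in reference_levels:
        for rep in range(videos_per_level):
            cell_seed = _child_seed(seed, idx)
            for field_on in (True, False):
                yield (
                    replace(
                        protocol_template,
                        glucose_level=float(level),
                        field_on=field_on,
                        seed=cell_seed,
                    ),
                    rep,
                )
            idx += 1


def generate_fixture_dataset(
    protocol_template: SimulationProtocol,
    reference_table: Sequence[float],
    videos_per_level: int,
    out_dir: str | Path,
    motion: MotionModel | None = None,
    seed: int = 0,
    dry_run: bool = False,
) -> pd.DataFrame:
    """Write a labelled video dataset and return its manifest.

    One TIFF per (glucose level, replicate, field condition); the manifest
    has 2 · len(levels) · videos_per_level rows and is deterministic for a
    fixed seed. With ``dry_run`` no files are written.
    """
    levels = [float(x) for x in reference_table]
    if not levels:
        raise InvalidParameterError("reference_table must be non-empty")
    if videos_per_level < 1:
        raise InvalidParameterError("videos_per_level must be >= 1")
    out_dir = Path(out_dir)
    rows = []
    for protocol, rep in iter_dataset_protocols(
        protocol_template, levels, videos_per_level, seed
    ):
        tag = "on" if protocol.field_on else "off"
        name = f"g{protocol.glucose_level:.0f}_r{rep}_{tag}.tif"
        if not dry_run:
            out_dir.mkdir(parents=True, exist_ok=True)
            video = simulate_recording(protocol, motion)
            write_video(video, out_dir / name)
        rows.append(
            {
                "path": name,
                "glucose_level": protocol.glucose_level,
                "field_on": protocol.field_on,
                "seed": protocol.seed,
            }
        )
    manifest = pd.DataFrame(rows)
    if not dry_run:
        manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest
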