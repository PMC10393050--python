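"""Speckle displacement tracking by normalized circular cross-correlation.

Each frame pair is zero-meaned and cross-correlated through the FFT; the
correlation peak location gives the rigid (dx, dy) shift of the later frame
relative to the earlier one, refined to sub-pixel precision with a 3-point
parabolic fit per axis. Speckle fills the frame, so circular correlation is
used without an aperture taper; edge wrap-around is part of the documented
convention rather than suppressed.

Coordinate convention: frames are indexed (row, col) = (y, x), origin at the
top-left; a positive dx moves the pattern toward larger column index. Shifts
describe frame_b relative to frame_a.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import DegenerateInputError, InvalidInputError
from .simulator import SpeckleVideo

__all__ = [
    "DisplacementSeries",
    "cross_correlate",
    "estimate_shift",
    "track_video",
]


@dataclass
class DisplacementSeries:
    """Per-frame-pair shift estimates at the video frame rate.

    dx, dy : estimated shifts [px], length = frames − 1
    peak : normalized correlation peak value per pair, in [−1, 1]; its time
        average is the standard speckle-quality metric of a recording.
    fps : sampling rate of the series [Hz]
    """

    dx: np.ndarray
    dy: np.ndarray
    peak: np.ndarray
    fps: float
    mode: str = "sequential"

    def __post_init__(self) -> None:
        if not (len(self.dx) == len(self.dy) == len(self.peak)):
            raise InvalidInputError("dx, dy, peak must have equal lengths")
        if np.any(np.abs(self.peak) > 1.0 + 1e-9):
            raise InvalidInputError("normalized peaks must lie in [-1, 1]")

    def __len__(self) -> int:
        return len(self.dx)

    @property
    def mean_peak(self) -> float:
        """Time-averaged peak correlation (recording quality metric)."""
        return float(np.mean(self.peak))

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        t = np.arange(len(self)) / self.fps
        pd.DataFrame(
            {"t": t, "dx": self.dx, "dy": self.dy, "peak": self.peak}
        ).to_csv(path, index=False)
        return path

    @classmethod
    def from_csv(cls, path: str | Path, mode: str = "sequential") -> "DisplacementSeries":
        df = pd.read_csv(path)
        if len(df) > 1:
            fps = 1.0 / float(df["t"].iloc[1] - df["t"].iloc[0])
        else:
            fps = 1.0
        return cls(
            dx=df["dx"].to_numpy(),
            dy=df["dy"].to_numpy(),
            peak=df["peak"].to_numpy(),
            fps=fps,
            mode=mode,
        )


def _center(frame: np.ndarray) -> tuple[np.ndarray, float]:
    frame = np.asarray(frame, dtype=np.float64)
    centered = frame - frame.mean()
    norm = float(np.sqrt(np.sum(centered * centered)))
    return centered, norm


def cross_correlate(frame_a: np.ndarray, frame_b: np.ndarray) -> np.ndarray:
    """Normalized zero-mean circular cross-correlation surface.

    Entry [ly, lx] is the Pearson-style correlation between frame_a and
    frame_b circularly shifted back by (lx, ly); in particular the value at
    lag (0, 0) equals the Pearson correlation of the two frames, and a pure
    circular shift of frame_a by (dx, dy) gives a peak of 1.0 at that lag.
    """
    frame_a = np.asarray(frame_a)
    frame_b = np.asarray(frame_b)
    if frame_a.shape != frame_b.shape:
        raise InvalidInputError(
            f"frame shapes differ: {frame_a.shape} vs {frame_b.shape}"
        )
    a, norm_a = _center(frame_a)
    b, norm_b = _center(frame_b)
    if norm_a == 0.0 or norm_b == 0.0:
        raise DegenerateInputError(
            "constant frame: normalized correlation is undefined"
        )
    fa = np.fft.rfft2(a)
    fb = np.fft.rfft2(b)
    surface = np.fft.irfft2(np.conj(fa) * fb, s=a.shape)
    return surface / (norm_a * norm_b)


def _wrap_lag(index: int, n: int) -> int:
    return index - n if index > n // 2 else index


def _parabolic_offset(c_minus: float, c0: float, c_plus: float) -> float:
    denom = c_minus - 2.0 * c0 + c_plus
    if denom == 0.0:
        return 0.0
    offset = 0.5 * (c_minus - c_plus) / denom
    return float(np.clip(offset, -0.5, 0.5))


def estimate_shift(
    surface: np.ndarray, subpixel: bool = True
) -> tuple[float, float, float]:
    """Locate the correlation peak; returns (dx, dy, peak value).

    The integer argmax is refined per axis with a 3-point parabolic fit when
    ``subpixel`` is set. Exact ties are broken by the smallest lag magnitude,
    then lexicographically on (dy, dx).
    """
    surface = np.asarray(surface, dtype=np.float64)
    if not np.all(np.isfinite(surface)):
        raise InvalidInputError("correlation surface contains non-finite values")
    ny, nx = surface.shape
    peak_value = surface.max()
    ties = np.argwhere(surface == peak_value)
    if len(ties) > 1:
        lags = np.array(
            [(_wrap_lag(iy, ny), _wrap_lag(ix, nx)) for iy, ix in ties], dtype=float
        )
        order = np.lexsort(
            (lags[:, 1], lags[:, 0], lags[:, 0] ** 2 + lags[:, 1] ** 2)
        )
        iy, ix = ties[order[0]]
    else:
        iy, ix = ties[0]
    dy = float(_wrap_lag(int(iy), ny))
    dx = float(_wrap_lag(int(ix), nx))
    if subpixel:
        dy += _parabolic_offset(
            surface[(iy - 1) % ny, ix], surface[iy, ix], surface[(iy + 1) % ny, ix]
        )
        dx += _parabolic_offset(
            surface[iy, (ix - 1) % nx], surface[iy, ix], surface[iy, (ix + 1) % nx]
        )
    return dx, dy, float(peak_value)


def _estimate_shifts_batch(
    surfaces: np.ndarray, subpixel: bool
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized argmax + parabolic refinement over a stack of surfaces."""
    n, ny, nx = surfaces.shape
    flat_idx = surfaces.reshape(n, -1).argmax(axis=1)
    iy = flat_idx // nx
    ix = flat_idx % nx
    rows = np.arange(n)
    peak = surfaces[rows, iy, ix]
    dy = np.where(iy > ny // 2, iy - ny, iy).astype(np.float64)
    dx = np.where(ix > nx // 2, ix - nx, ix).astype(np.float64)
    if subpixel:
        cym = surfaces[rows, (iy - 1) % ny, ix]
        cyp = surfaces[rows, (iy + 1) % ny, ix]
        cxm = surfaces[rows, iy, (ix - 1) % nx]
        cxp = surfaces[rows, iy, (ix + 1) % nx]
        dy_den = cym - 2.0 * peak + cyp
        dx_den = cxm - 2.0 * peak + cxp
        with np.errstate(divide="ignore", invalid="ignore"):
            off_y = np.where(dy_den != 0, 0.5 * (cym - cyp) / dy_den, 0.0)
            off_x = np.where(dx_den != 0, 0.5 * (cxm - cxp) / dx_den, 0.0)
        dy += np.clip(off_y, -0.5, 0.5)
        dx += np.clip(off_x, -0.5, 0.5)
    return dx, dy, peak


def track_video(
    video: SpeckleVideo | np.ndarray,
    mode: str = "sequential",
    subpixel: bool = True,
) -> DisplacementSeries:
    """Displacement time series of a whole recording.

    ``sequential`` correlates consecutive frame pairs (the series measures
    per-frame velocity in pixels/frame); ``fixed_reference`` correlates each
    frame against frame 0 (absolute position while decorrelation is mild).
    The series length is frames − 1.
    """
    if isinstance(video, SpeckleVideo):
        frames = video.frames
        fps = video.protocol.fps
    else:
        frames = np.asarray(video)
        fps = 1.0
    if frames.ndim != 3 or frames.shape[0] < 2:
        raise InvalidInputError("video must hold at least 2 frames")
    if mode not in ("sequential", "fixed_reference"):
        raise InvalidInputError(f"unknown tracking mode: {mode!r}")

    stack = np.asarray(frames, dtype=np.float64)
    centered = stack - stack.mean(axis=(1, 2), keepdims=True)
    norms = np.sqrt(np.sum(centered * centered, axis=(1, 2)))
    if np.any(norms == 0.0):
        raise DegenerateInputError("constant frame encountered during tracking")
    ffts = np.fft.rfft2(centered)

    if mode == "sequential":
        spectra = np.conj(ffts[:-1]) * ffts[1:]
        denom = norms[:-1] * norms[1:]
    else:
        spectra = np.conj(ffts[0])[None, ...] * ffts[1:]
        denom = norms[0] * norms[1:]
    surfaces = np.fft.irfft2(spectra, s=stack.shape[1:])
    surfaces /= denom[:, None, None]

    dx, dy, peak = _estimate_shifts_batch(surfaces, subpixel)
    return DisplacementSeries(
        dx=dx, dy=dy, peak=np.clip(peak, -1.0, 1.0), fps=fps, mode=mode
    )
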