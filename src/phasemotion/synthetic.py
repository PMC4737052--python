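"""Deterministic, seeded generators for synthetic test stimuli.

All generators are pure functions of their arguments (and seed): repeated
calls are bit-identical. Ground truth (true direction, per-frame object
positions / edge offsets) is stored in ``VideoStream.meta`` so detectors can
be scored without external data. Sub-pixel positions are rendered with
linear interpolation (edges, squares) or bilinear warping (textures).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.ndimage import shift as nd_shift

from .video_core import VideoStream

__all__ = [
    "DegradationSpec",
    "moving_edge_video",
    "moving_square_video",
    "drifting_grating_video",
    "translating_texture_video",
    "degrade",
    "edge_mask",
    "square_mask",
]


def _n_frames(duration: float, fs: float) -> int:
    n = int(round(duration * fs))
    if n < 2:
        raise ValueError("duration*fs must give at least 2 frames")
    return n


def moving_edge_video(
    kind: str = "on",
    velocity: tuple[float, float] = (40.0, 0.0),
    size: tuple[int, int] = (64, 64),
    duration: float = 0.5,
    fs: float = 50.0,
    contrast: float = 1.0,
    background: float = 0.0,
    start_frac: float = 0.25,
) -> VideoStream:
    """Straight edge translating at constant velocity (px/s).

    The edge is perpendicular to the velocity; for an ON edge the bright
    side trails the motion (dark-to-bright step sweeping forward). The
    boundary pixel is linearly interpolated for sub-pixel positions. With
    ``background=0`` and ``contrast=1`` the OFF edge is exactly
    ``1 - ON`` frame by frame.
    """
    Px, Py = size
    if Px < 2 or Py < 2:
        raise ValueError("frame must be at least 2x2 pixels")
    if kind not in ("on", "off"):
        raise ValueError("kind must be 'on' or 'off'")
    T = _n_frames(duration, fs)
    vx, vy = float(velocity[0]), float(velocity[1])
    speed = float(np.hypot(vx, vy))
    if speed == 0:
        nx, ny = 1.0, 0.0
    else:
        nx, ny = vx / speed, vy / speed
    x = np.arange(Px, dtype=np.float64)
    y = np.arange(Py, dtype=np.float64)
    X, Y = np.meshgrid(x, y)
    # signed distance of each pixel along the motion direction, measured
    # from the edge's starting position
    x0 = (Px - 1) / 2.0 - nx * start_frac * min(Px, Py)
    y0 = (Py - 1) / 2.0 - ny * start_frac * min(Px, Py)
    d = (X - x0) * nx + (Y - y0) * ny
    frames = np.empty((T, Py, Px))
    offsets = np.empty(T)
    for t in range(T):
        s = speed * t / fs
        offsets[t] = s
        step = np.clip(s - d + 0.5, 0.0, 1.0)  # 1 behind the edge, 0 ahead
        if kind == "off":
            step = 1.0 - step
        frames[t] = background + contrast * step
    meta = {
        "kind": f"{kind}_edge",
        "velocity": (vx, vy),
        "theta_true": float(np.mod(np.arctan2(vy, vx), 2 * np.pi)),
        "normal": (nx, ny),
        "origin": (x0, y0),
        "edge_offsets": offsets,
    }
    return VideoStream(frames, frame_rate=fs, meta=meta)


def edge_mask(video: VideoStream, t: int, halfwidth: float = 2.0) -> np.ndarray:
    """Pixels within ``halfwidth`` of the edge line at frame t."""
    nx, ny = video.meta["normal"]
    x0, y0 = video.meta["origin"]
    s = video.meta["edge_offsets"][t]
    X, Y = np.meshgrid(np.arange(video.width), np.arange(video.height))
    d = (X - x0) * nx + (Y - y0) * ny
    return np.abs(d - s) <= halfwidth


def moving_square_video(
    side: float = 20.0,
    velocity: tuple[float, float] = (40.0, 0.0),
    size: tuple[int, int] = (96, 96),
    duration: float = 0.5,
    fs: float = 50.0,
    foreground: float = 1.0,
    background: float = 0.0,
    start: tuple[float, float] | None = None,
) -> VideoStream:
    """Bright square translating over a uniform background.

    Edges are antialiased by pixel-coverage (separable linear
    interpolation), so sub-pixel shifts between frames are rendered.
    """
    Px, Py = size
    if Px < 2 or Py < 2:
        raise ValueError("frame must be at least 2x2 pixels")
    T = _n_frames(duration, fs)
    vx, vy = float(velocity[0]), float(velocity[1])
    if start is None:
        sweep = np.hypot(vx, vy) * (T - 1) / fs
        start = (
            (Px - 1) / 2.0 - side / 2.0 - (vx / max(np.hypot(vx, vy), 1e-12)) * sweep / 2.0,
            (Py - 1) / 2.0 - side / 2.0 - (vy / max(np.hypot(vx, vy), 1e-12)) * sweep / 2.0,
        ) if (vx, vy) != (0.0, 0.0) else ((Px - side) / 2.0, (Py - side) / 2.0)
    x = np.arange(Px, dtype=np.float64)
    y = np.arange(Py, dtype=np.float64)
    frames = np.empty((T, Py, Px))
    positions = np.empty((T, 2))
    for t in range(T):
        px = start[0] + vx * t / fs
        py = start[1] + vy * t / fs
        positions[t] = (px, py)
        covx = np.clip(np.minimum(x + 0.5, px + side) - np.maximum(x - 0.5, px), 0.0, 1.0)
        covy = np.clip(np.minimum(y + 0.5, py + side) - np.maximum(y - 0.5, py), 0.0, 1.0)
        frames[t] = background + (foreground - background) * np.outer(covy, covx)
    meta = {
        "kind": "square",
        "velocity": (vx, vy),
        "theta_true": float(np.mod(np.arctan2(vy, vx), 2 * np.pi)),
        "side": float(side),
        "positions": positions,
    }
    return VideoStream(frames, frame_rate=fs, meta=meta)


def square_mask(video: VideoStream, t: int) -> np.ndarray:
    """Boolean footprint of the square at frame t (pixels > half covered)."""
    px, py = video.meta["positions"][t]
    side = video.meta["side"]
    x = np.arange(video.width, dtype=np.float64)
    y = np.arange(video.height, dtype=np.float64)
    covx = np.clip(np.minimum(x + 0.5, px + side) - np.maximum(x - 0.5, px), 0.0, 1.0)
    covy = np.clip(np.minimum(y + 0.5, py + side) - np.maximum(y - 0.5, py), 0.0, 1.0)
    return np.outer(covy, covx) > 0.5


def drifting_grating_video(
    omega: float,
    velocity: float = 10.0,
    size: tuple[int, int] = (64, 64),
    duration: float = 0.5,
    fs: float = 50.0,
    contrast: float = 1.0,
    mean: float = 0.5,
) -> VideoStream:
    """Horizontal sinusoidal grating drifting along x:
    ``u = mean + (contrast/2) * cos(omega * (x - v*t))``.

    The temporal frequency at a fixed pixel is ``omega * velocity`` rad/s;
    a warning is raised when the per-frame phase step reaches pi (temporal
    aliasing).
    """
    Px, Py = size
    if abs(omega) > np.pi:
        raise ValueError("spatial frequency must satisfy |omega| <= pi rad/px")
    if abs(omega * velocity) / fs >= np.pi:
        warnings.warn("temporal aliasing: |omega*v|/fs >= pi per frame")
    T = _n_frames(duration, fs)
    x = np.arange(Px, dtype=np.float64)
    frames = np.empty((T, Py, Px))
    for t in range(T):
        row = mean + (contrast / 2.0) * np.cos(omega * (x - velocity * t / fs))
        frames[t] = np.broadcast_to(row, (Py, Px))
    meta = {
        "kind": "grating",
        "omega": float(omega),
        "velocity": (float(velocity), 0.0),
        "theta_true": 0.0 if velocity >= 0 else float(np.pi),
        "temporal_frequency": float(omega * velocity),
    }
    return VideoStream(frames, frame_rate=fs, meta=meta)


def translating_texture_video(
    seed: int = 0,
    velocity: tuple[float, float] = (40.0, 0.0),
    size: tuple[int, int] = (64, 64),
    duration: float = 0.5,
    fs: float = 50.0,
    contrast: float = 1.0,
    mean: float = 0.5,
    smooth: float = 1.0,
) -> VideoStream:
    """Seeded random texture translating with periodic wrap.

    Frame t equals frame 0 shifted by ``(vx*t/fs, vy*t/fs)`` modulo the
    frame size, using bilinear interpolation for sub-pixel shifts.
    """
    Px, Py = size
    rng = np.random.default_rng(seed)
    tex = rng.random((Py, Px))
    if smooth > 0:
        tex = gaussian_filter(tex, smooth, mode="wrap")
    tex = tex - tex.min()
    rngv = tex.max()
    if rngv > 0:
        tex = tex / rngv
    tex = mean - contrast / 2.0 + contrast * tex
    T = _n_frames(duration, fs)
    vx, vy = float(velocity[0]), float(velocity[1])
    frames = np.empty((T, Py, Px))
    for t in range(T):
        frames[t] = nd_shift(tex, (vy * t / fs, vx * t / fs), order=1, mode="grid-wrap")
    meta = {
        "kind": "texture",
        "seed": int(seed),
        "velocity": (vx, vy),
        "theta_true": float(np.mod(np.arctan2(vy, vx), 2 * np.pi)),
    }
    return VideoStream(frames, frame_rate=fs, meta=meta)


@dataclass(frozen=True)
class DegradationSpec:
    """Affine contrast/luminance change plus optional additive noise.

    The affine map ``u -> contrast_factor*u + mean_shift`` must keep the
    video inside [0, 1]; seeded Gaussian noise with standard deviation
    ``noise_sigma`` (fraction of the full [0, 1] luminance range) is then
    added and the result clipped back to [0, 1].
    """

    contrast_factor: float = 1.0
    mean_shift: float = 0.0
    noise_sigma: float = 0.0
    seed: int | None = None

    def __post_init__(self):
        if not (0.0 < self.contrast_factor <= 1.0):
            raise ValueError("contrast_factor must be in (0, 1]")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be nonnegative")


def degrade(video: VideoStream, spec: DegradationSpec) -> VideoStream:
    """Apply a :class:`DegradationSpec` to a video; see the spec docstring."""
    lo = spec.contrast_factor * float(video.data.min()) + spec.mean_shift
    hi = spec.contrast_factor * float(video.data.max()) + spec.mean_shift
    if lo < -1e-9 or hi > 1.0 + 1e-9:
        raise ValueError(
            f"affine map drives intensities to [{lo:.3f}, {hi:.3f}], outside [0, 1]"
        )
    data = spec.contrast_factor * video.data + spec.mean_shift
    clipped_fraction = 0.0
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        data = data + rng.normal(0.0, spec.noise_sigma, size=data.shape)
        out = np.clip(data, 0.0, 1.0)
        clipped_fraction = float(np.mean(out != data))
        data = out
    meta = dict(video.meta)
    meta["degradation"] = {
        "contrast_factor": spec.contrast_factor,
        "mean_shift": spec.mean_shift,
        "noise_sigma": spec.noise_sigma,
        "seed": spec.seed,
        "clipped_fraction": clipped_fraction,
    }
    return VideoStream(data, frame_rate=video.frame_rate, meta=meta)
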