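"""Frames, overlapping block grids, Gaussian windows and block extraction.

Pixel coordinates are 1-based in the public API (the (1,1) pixel is the
top-left corner of the frame); internally everything is 0-based. Block
centers sit at ``(k*b0 + 1, l*b0 + 1)`` so that block ``(0, 0)`` is centered
on pixel ``(1, 1)``. Blocks that overhang the frame boundary are zero-padded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "VideoStream",
    "BlockGrid",
    "GaussianWindow",
    "make_block_grid",
    "make_gaussian_window",
    "extract_block",
    "insert_block",
    "as_frame",
    "read_video",
    "write_frames",
    "DEFAULT_SIGMA",
    "DEFAULT_BLOCK",
    "DEFAULT_SPACING",
    "DEFAULT_FRAME_RATE",
]

DEFAULT_SIGMA = 4.0
DEFAULT_BLOCK = 32
DEFAULT_SPACING = 6
DEFAULT_FRAME_RATE = 50.0

_IMAGE_SUFFIXES = (".png", ".tif", ".tiff", ".jpg", ".jpeg", ".bmp")


def as_frame(pixels) -> np.ndarray:
    """Validate and return a 2D float64 intensity frame."""
    frame = np.asarray(pixels, dtype=np.float64)
    if frame.ndim != 2 or frame.shape[0] < 1 or frame.shape[1] < 1:
        raise ValueError(f"frame must be a non-empty 2D array, got shape {frame.shape}")
    if not np.all(np.isfinite(frame)):
        raise ValueError("frame contains non-finite values")
    return frame


@dataclass
class VideoStream:
    """An ordered stack of equally sized grayscale frames.

    Attributes
    ----------
    data : ndarray, shape (T, Py, Px)
        Frame stack; axis 0 is time, axis 1 is y (rows), axis 2 is x.
    frame_rate : float
        Frames per second; must be positive.
    meta : dict
        Free-form metadata (generators store ground truth here).
    """

    data: np.ndarray
    frame_rate: float = DEFAULT_FRAME_RATE
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError("video data must have shape (T, Py, Px)")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def height(self) -> int:
        return self.data.shape[1]

    @property
    def width(self) -> int:
        return self.data.shape[2]

    @property
    def dt(self) -> float:
        return 1.0 / self.frame_rate

    def frame(self, t: int) -> np.ndarray:
        return self.data[t]

    def scaled(self, factor: float) -> "VideoStream":
        """Return a copy with intensities multiplied by ``factor``."""
        return VideoStream(self.data * factor, self.frame_rate, dict(self.meta))


@dataclass(frozen=True)
class BlockGrid:
    """Overlapping block tiling with spacing ``b0`` and block side ``M``.

    Block ``(k, l)`` is centered at 1-based pixel ``(k*b0 + 1, l*b0 + 1)``;
    ``k`` indexes x (columns), ``l`` indexes y (rows).
    """

    Px: int
    Py: int
    b0: int
    M: int
    K: int
    L: int

    def center(self, k: int, l: int) -> tuple[int, int]:
        """1-based pixel coordinates (cx, cy) of the center of block (k, l)."""
        if not (0 <= k < self.K and 0 <= l < self.L):
            raise ValueError(f"block index ({k},{l}) outside grid {self.K}x{self.L}")
        return (k * self.b0 + 1, l * self.b0 + 1)

    @property
    def centers(self) -> list[tuple[int, int, int, int]]:
        """List of (k, l, cx, cy) for all blocks."""
        return [
            (k, l, k * self.b0 + 1, l * self.b0 + 1)
            for k in range(self.K)
            for l in range(self.L)
        ]


def make_block_grid(Px: int, Py: int, b0: int, M: int = DEFAULT_BLOCK) -> BlockGrid:
    """Build the overlapping block grid for a Px x Py frame.

    The number of blocks along x is ``K = floor((Px - 1)/b0) + 1``, i.e. all
    k >= 0 with ``k*b0 + 1 <= Px`` (likewise along y).
    """
    if Px < 1 or Py < 1 or b0 < 1:
        raise ValueError("Px, Py and b0 must be positive integers")
    K = (int(Px) - 1) // int(b0) + 1
    L = (int(Py) - 1) // int(b0) + 1
    return BlockGrid(Px=int(Px), Py=int(Py), b0=int(b0), M=int(M), K=K, L=L)


@dataclass(frozen=True)
class GaussianWindow:
    """Isotropic Gaussian weights on an M x M block, peak 1 at the center.

    For even M the center sits at 0-based patch index (M/2, M/2); patch
    offsets run over ``-M/2 .. M/2 - 1`` along both axes.
    """

    sigma: float
    M: int
    weights: np.ndarray  # (M, M), indexed [dy + M//2, dx + M//2]

    def weight_at(self, dx: int, dy: int) -> float:
        """Weight at offset (dx, dy) from the window center."""
        return float(self.weights[dy + self.M // 2, dx + self.M // 2])


def make_gaussian_window(sigma: float, M: int = DEFAULT_BLOCK) -> GaussianWindow:
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if M < 2 or M % 2 != 0:
        raise ValueError("M must be a positive even integer")
    offsets = np.arange(M) - M // 2
    dx2 = offsets[None, :] ** 2
    dy2 = offsets[:, None] ** 2
    weights = np.exp(-(dx2 + dy2) / (2.0 * sigma**2))
    return GaussianWindow(sigma=float(sigma), M=int(M), weights=weights)


def extract_block(frame: np.ndarray, center: tuple[int, int], M: int) -> np.ndarray:
    """Zero-padded M x M patch around a 1-based pixel ``center = (cx, cy)``.

    The patch covers offsets ``-M/2 .. M/2 - 1`` around the center; positions
    outside the frame are filled with 0.
    """
    frame = as_frame(frame)
    H, W = frame.shape
    cx, cy = center
    if not (1 <= cx <= W and 1 <= cy <= H):
        raise ValueError(f"center {center} outside frame of size ({W},{H})")
    half = M // 2
    x0 = (cx - 1) - half
    y0 = (cy - 1) - half
    patch = np.zeros((M, M), dtype=np.float64)
    ys0, ys1 = max(0, y0), min(H, y0 + M)
    xs0, xs1 = max(0, x0), min(W, x0 + M)
    if ys1 > ys0 and xs1 > xs0:
        patch[ys0 - y0 : ys1 - y0, xs0 - x0 : xs1 - x0] = frame[ys0:ys1, xs0:xs1]
    return patch


def insert_block(frame: np.ndarray, patch: np.ndarray, center: tuple[int, int]) -> np.ndarray:
    """Write a patch back at ``center`` (inverse of :func:`extract_block`).

    Out-of-frame patch positions are dropped. Returns a modified copy.
    """
    frame = as_frame(frame).copy()
    H, W = frame.shape
    M = patch.shape[0]
    cx, cy = center
    half = M // 2
    x0 = (cx - 1) - half
    y0 = (cy - 1) - half
    ys0, ys1 = max(0, y0), min(H, y0 + M)
    xs0, xs1 = max(0, x0), min(W, x0 + M)
    if ys1 > ys0 and xs1 > xs0:
        frame[ys0:ys1, xs0:xs1] = patch[ys0 - y0 : ys1 - y0, xs0 - x0 : xs1 - x0]
    return frame


def _to_gray01(img: np.ndarray) -> np.ndarray:
    arr = np.asarray(img)
    if arr.ndim == 3:
        # RGB(A) -> luminance
        arr = arr[..., :3].astype(np.float64) @ np.array([0.299, 0.587, 0.114])
    arr = arr.astype(np.float64)
    if np.issubdtype(np.asarray(img).dtype, np.integer):
        arr = arr / float(np.iinfo(np.asarray(img).dtype).max)
    return arr


def read_video(path, frame_rate: float = DEFAULT_FRAME_RATE) -> VideoStream:
    """Read a video from an image-sequence directory or a container file.

    Directories are scanned for PNG/TIFF/JPEG frames in sorted filename
    order; 8/16-bit integer images are rescaled to [0, 1] and color frames
    converted to grayscale luminance.
    """
    import imageio.v3 as iio

    p = Path(path)
    frames = []
    if p.is_dir():
        files = sorted(f for f in p.iterdir() if f.suffix.lower() in _IMAGE_SUFFIXES)
        if not files:
            raise ValueError(f"no image frames found in {p}")
        for f in files:
            frames.append(_to_gray01(iio.imread(f)))
    else:
        for img in iio.imiter(p):
            frames.append(_to_gray01(img))
    data = np.stack(frames, axis=0)
    return VideoStream(data, frame_rate=frame_rate, meta={"source": str(p)})


def write_frames(video: VideoStream, out_dir, prefix: str = "frame") -> list[Path]:
    """Write a video as an 8-bit grayscale PNG sequence; returns the paths."""
    import imageio.v3 as iio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for t in range(video.n_frames):
        arr = np.clip(video.data[t], 0.0, 1.0)
        img = np.round(arr * 255.0).astype(np.uint8)
        fp = out / f"{prefix}_{t:05d}.png"
        iio.imwrite(fp, img)
        paths.append(fp)
    return paths
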