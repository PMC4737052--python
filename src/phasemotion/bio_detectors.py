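"""Reichardt and Barlow-Levick reference motion detectors.

Both detectors operate on a video that is first blurred with a Gaussian and
subsampled at the block-grid centers, giving the same output geometry as the
phase-based detector. Temporal filtering uses first-order exponential
filters (exact discretization of a continuous first-order system at the
frame interval), with the high-pass stage placed in front of the low-pass
stage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.signal import lfilter

from .video_core import (
    DEFAULT_SIGMA,
    DEFAULT_SPACING,
    DEFAULT_BLOCK,
    VideoStream,
    make_block_grid,
)

__all__ = [
    "FilterSpec",
    "DetectorGridOutput",
    "temporal_filter",
    "reichardt_response",
    "barlow_levick_response",
    "detector_array",
]


@dataclass(frozen=True)
class FilterSpec:
    """First-order temporal filter: kind in {"low_pass", "high_pass"},
    time constant tau in seconds."""

    kind: str
    tau: float

    def __post_init__(self):
        if self.kind not in ("low_pass", "high_pass"):
            raise ValueError(f"unknown filter kind {self.kind!r}")
        if self.tau <= 0:
            raise ValueError("tau must be positive")


def temporal_filter(signal: np.ndarray, spec: FilterSpec, fs: float) -> np.ndarray:
    """Apply a first-order exponential filter along axis 0 (time).

    Low-pass: ``y[t] = alpha*x[t] + (1 - alpha)*y[t-1]`` with
    ``alpha = 1 - exp(-1/(fs*tau))`` and zero initial state; high-pass is
    the complement ``x - lowpass(x)``.
    """
    if fs <= 0:
        raise ValueError("fs must be positive")
    x = np.asarray(signal, dtype=np.float64)
    alpha = 1.0 - np.exp(-1.0 / (fs * spec.tau))
    low = lfilter([alpha], [1.0, -(1.0 - alpha)], x, axis=0)
    return x - low if spec.kind == "high_pass" else low


def _paired_response(
    u1: np.ndarray, u2: np.ndarray, tau_hp: float, tau_lp: float, fs: float, kind: str
) -> np.ndarray:
    u1 = np.asarray(u1, dtype=np.float64)
    u2 = np.asarray(u2, dtype=np.float64)
    if u1.shape != u2.shape:
        raise ValueError("input time series must have equal shapes")
    hp = FilterSpec("high_pass", tau_hp)
    lp = FilterSpec("low_pass", tau_lp)
    f1 = temporal_filter(u1, hp, fs)
    f2 = temporal_filter(u2, hp, fs)
    d1 = temporal_filter(f1, lp, fs)
    d2 = temporal_filter(f2, lp, fs)
    if kind == "reichardt":
        # correlate each high-passed signal with the delayed (low-passed)
        # version of its neighbor; antisymmetric under input swap
        return f2 * d1 - f1 * d2
    if kind == "barlow_levick":
        # preferred-direction signal suppressed by delayed inhibition from
        # the neighbor; opponent pair gives the signed response
        o_right = f1 - d2
        o_left = f2 - d1
        return o_right - o_left
    raise ValueError(f"unknown detector kind {kind!r}")


def reichardt_response(
    u1: np.ndarray, u2: np.ndarray, tau_hp: float = 0.2, tau_lp: float = 0.3, fs: float = 50.0
) -> np.ndarray:
    """Elaborated Reichardt correlator output for two input time series.

    Inputs are high-passed (tau_hp), cross-multiplied with the low-passed
    (tau_lp) copy of the other channel, and the mirrored product subtracted.
    Output is positive for motion from u1 toward u2, exactly negated when
    the inputs are swapped, and quadratic in input contrast.
    """
    return _paired_response(u1, u2, tau_hp, tau_lp, fs, "reichardt")


def barlow_levick_response(
    u1: np.ndarray, u2: np.ndarray, tau_hp: float = 0.25, tau_lp: float = 0.3, fs: float = 50.0
) -> np.ndarray:
    """Barlow-Levick opponent output for two input time series.

    Each half-detector subtracts the delayed (inhibition) signal of its
    neighbor from its own high-passed signal; the signed output is the
    difference of the two opposing half-detectors. Linear in contrast.
    """
    return _paired_response(u1, u2, tau_hp, tau_lp, fs, "barlow_levick")


@dataclass
class DetectorGridOutput:
    """Signed responses of a detector array on the block-grid centers.

    ``h`` and ``v`` have shape (T, K, L); ``h[t, k, l]`` is the horizontal
    response of the pair (k, l)-(k+1, l) (zero in the last column),
    ``v[t, k, l]`` the vertical response of (k, l)-(k, l+1) (zero in the
    last row). ``flags`` marks |response| above threshold.
    """

    h: np.ndarray
    v: np.ndarray
    flags: np.ndarray
    threshold: float


def detector_array(
    video: VideoStream,
    kind: str = "reichardt",
    sigma: float = DEFAULT_SIGMA,
    b0: int = DEFAULT_SPACING,
    threshold: float = 2.0,
    tau_hp: float | None = None,
    tau_lp: float = 0.3,
) -> DetectorGridOutput:
    """Run a 2D array of paired detectors on a blurred, subsampled video.

    The video is blurred with a Gaussian of the given sigma, sampled at the
    block-grid centers (same grid as the phase detector), and horizontal /
    vertical detector pairs are run between neighboring centers.
    """
    if video.n_frames < 2:
        raise ValueError("need at least 2 frames")
    if kind not in ("reichardt", "barlow_levick"):
        raise ValueError(f"unknown detector kind {kind!r}")
    if tau_hp is None:
        tau_hp = 0.2 if kind == "reichardt" else 0.25
    grid = make_block_grid(video.width, video.height, b0, DEFAULT_BLOCK)
    blurred = np.stack([gaussian_filter(video.frame(t), sigma) for t in range(video.n_frames)])
    cx = np.array([k * grid.b0 for k in range(grid.K)])
    cy = np.array([l * grid.b0 for l in range(grid.L)])
    # samples S[t, k, l]
    S = blurred[:, cy[None, :], cx[:, None]]
    fs = video.frame_rate
    resp = reichardt_response if kind == "reichardt" else barlow_levick_response
    h = np.zeros_like(S)
    v = np.zeros_like(S)
    if grid.K > 1:
        h[:, :-1, :] = resp(S[:, :-1, :], S[:, 1:, :], tau_hp, tau_lp, fs)
    if grid.L > 1:
        v[:, :, :-1] = resp(S[:, :, :-1], S[:, :, 1:], tau_hp, tau_lp, fs)
    flags = (np.abs(h) > threshold) | (np.abs(v) > threshold)
    return DetectorGridOutput(h=h, v=v, flags=flags, threshold=float(threshold))
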