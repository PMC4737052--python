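"""Radon-transform motion detection on local phase-change fields.

The phase-change field of each block, restricted to the circular frequency
domain ``C = {omega_x^2 + omega_y^2 < pi^2}`` (``m^2 + n^2 < (M/2)^2`` in
index units), is integrated along discrete lines: every grid point of C is
assigned to the nearest-rho line at each of ``n_theta`` uniformly spaced
angles in [0, pi). ``R(rho, theta)`` is the sum of field values on a line
and ``c(rho, theta)`` the number of contributing points (the discrete line
length). The Phase Motion Indicator is

    PMI = max_theta sum_rho |R(rho, theta) / c(rho, theta)|

over populated bins; blocks whose PMI exceeds a threshold are flagged as
moving and a direction is read out from the sign of the positive-rho lobe
at the argmax angle.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np

from .video_core import (
    DEFAULT_BLOCK,
    DEFAULT_SIGMA,
    DEFAULT_SPACING,
    VideoStream,
    make_block_grid,
    make_gaussian_window,
)
from .local_phase import (
    block_stft,
    default_epsilon,
    denoise_phase_change,
    frequency_grid,
    phase_time_derivative,
)

__all__ = [
    "BoundedDomain",
    "Sinogram",
    "MotionMap",
    "DetectorConfig",
    "bounded_radon",
    "pmi",
    "motion_direction",
    "plane_reference_pmi",
    "default_threshold",
    "detect_motion",
    "segment_motion",
]

DEFAULT_N_THETA = 16


@dataclass(frozen=True)
class BoundedDomain:
    """Circular bounded frequency domain on an M x M grid."""

    M: int
    mask: np.ndarray  # (M, M) bool, indexed [n_idx, m_idx]
    m_idx: np.ndarray  # signed x-frequency index of the points in the domain
    n_idx: np.ndarray  # signed y-frequency index of the points in the domain

    @classmethod
    def for_block(cls, M: int) -> "BoundedDomain":
        idx = np.arange(M) - M // 2
        mm, nn = np.meshgrid(idx, idx, indexing="xy")  # mm varies along axis 1
        mask = mm**2 + nn**2 < (M // 2) ** 2
        if not mask.any():
            raise ValueError(f"empty bounded domain for M={M}")
        return cls(M=M, mask=mask, m_idx=mm[mask].astype(np.float64), n_idx=nn[mask].astype(np.float64))


@dataclass
class Sinogram:
    """Discrete line sums R and line lengths c on a (theta, rho) grid."""

    R: np.ndarray       # (n_theta, n_rho) line sums
    counts: np.ndarray  # (n_theta, n_rho) number of points per line
    thetas: np.ndarray  # (n_theta,) angles in [0, pi)
    rhos: np.ndarray    # (n_rho,) signed offsets in frequency-index units

    def profile(self) -> np.ndarray:
        """|R/c| with empty bins set to 0, shape (n_theta, n_rho)."""
        out = np.zeros_like(self.R)
        np.divide(np.abs(self.R), self.counts, out=out, where=self.counts > 0)
        return out


class _RadonBinning:
    """Precomputed nearest-rho binning of the bounded domain points."""

    def __init__(self, domain: BoundedDomain, n_theta: int):
        if n_theta < 2:
            raise ValueError("n_theta must be >= 2")
        self.domain = domain
        self.thetas = np.arange(n_theta) * np.pi / n_theta
        rmax = domain.M // 2
        self.rhos = np.arange(-rmax, rmax + 1, dtype=np.float64)
        n_rho = self.rhos.size
        npts = domain.m_idx.size
        # bin index of each domain point at each angle
        self.bins = np.empty((n_theta, npts), dtype=np.intp)
        self.counts = np.zeros((n_theta, n_rho), dtype=np.float64)
        for i, th in enumerate(self.thetas):
            rho = domain.m_idx * np.cos(th) + domain.n_idx * np.sin(th)
            b = np.rint(rho).astype(np.intp) + rmax
            self.bins[i] = b
            self.counts[i] = np.bincount(b, minlength=n_rho)

    def sums(self, values: np.ndarray) -> np.ndarray:
        """Line sums for field values at the domain points.

        ``values`` has shape (..., npts); returns (..., n_theta, n_rho).
        """
        values = np.asarray(values, dtype=np.float64)
        lead = values.shape[:-1]
        flat = values.reshape(-1, values.shape[-1])
        n_theta, n_rho = self.counts.shape
        out = np.zeros((flat.shape[0], n_theta, n_rho), dtype=np.float64)
        for i in range(n_theta):
            b = self.bins[i]
            for j in range(flat.shape[0]):
                out[j, i] = np.bincount(b, weights=flat[j], minlength=n_rho)
        return out.reshape(*lead, n_theta, n_rho)


_binning_cache: dict[tuple[int, int], _RadonBinning] = {}


def _get_binning(M: int, n_theta: int) -> _RadonBinning:
    key = (M, n_theta)
    if key not in _binning_cache:
        _binning_cache[key] = _RadonBinning(BoundedDomain.for_block(M), n_theta)
    return _binning_cache[key]


def bounded_radon(
    field: np.ndarray, domain: BoundedDomain, n_theta: int = DEFAULT_N_THETA
) -> Sinogram:
    """Discrete Radon transform of a frequency-grid field over the domain.

    Each domain grid point contributes its field value to the nearest-rho
    line at every angle; ``counts`` records how many points landed in each
    (rho, theta) bin.
    """
    field = np.asarray(field, dtype=np.float64)
    if field.shape != (domain.M, domain.M):
        raise ValueError(f"field shape {field.shape} does not match domain M={domain.M}")
    if not np.all(np.isfinite(field)):
        raise ValueError("field must be finite")
    binning = _get_binning(domain.M, n_theta)
    values = field[domain.mask]
    R = binning.sums(values)
    return Sinogram(R=R, counts=binning.counts.copy(), thetas=binning.thetas.copy(), rhos=binning.rhos.copy())


def pmi(sinogram: Sinogram) -> float:
    """Phase Motion Indicator: max over theta of sum_rho |R/c|."""
    if not (sinogram.counts > 0).any():
        raise ValueError("sinogram has no populated bins")
    return float(sinogram.profile().sum(axis=1).max())


def motion_direction(sinogram: Sinogram) -> float:
    """Direction of motion in [0, 2*pi) read out from the sinogram.

    At the angle ``alpha`` maximizing ``sum_rho |R/c|``, the sign of the
    positive-rho average decides between ``alpha`` and ``alpha + pi``.
    """
    prof = sinogram.profile()
    scores = prof.sum(axis=1)
    if not np.any(scores > 0):
        raise ValueError("motion direction undefined: all line integrals are zero")
    i = int(np.argmax(scores))
    alpha = float(sinogram.thetas[i])
    pos = sinogram.rhos > 0
    ok = pos & (sinogram.counts[i] > 0)
    s = float(np.sum(sinogram.R[i, ok] / sinogram.counts[i, ok]))
    theta = np.pi * (np.sign(s) + 1.0) / 2.0 + alpha
    return float(np.mod(theta, 2.0 * np.pi))


def plane_reference_pmi(
    M: int, n_theta: int = DEFAULT_N_THETA, speed: float = 10.0, n_dirs: int = 16
) -> float:
    """Median PMI of pure planar phase-change fields at the given speed.

    The reference fields are ``-vx*omega_x - vy*omega_y`` (rad/s) for
    velocities of magnitude ``speed`` px/s at ``n_dirs`` uniformly spaced
    directions; used to set detection thresholds.
    """
    wx, wy = frequency_grid(M)
    domain = BoundedDomain.for_block(M)
    vals = []
    for phi in np.arange(n_dirs) * (2.0 * np.pi / n_dirs):
        f = -speed * np.cos(phi) * wx - speed * np.sin(phi) * wy
        vals.append(pmi(bounded_radon(f, domain, n_theta)))
    return float(np.median(vals))


def default_threshold(
    M: int, n_theta: int = DEFAULT_N_THETA, speed: float = 10.0, factor: float = 0.6
) -> float:
    """Default PMI threshold: ``factor`` times the planar reference PMI."""
    return factor * plane_reference_pmi(M, n_theta, speed)


@dataclass
class DetectorConfig:
    """Configuration of the phase-based motion detector.

    ``eps`` and ``threshold`` default to automatic values derived from the
    video (see :func:`default_epsilon`) and from the planar reference PMI.
    ``threshold_scale`` multiplies the threshold (e.g. 1.6 for noisy video).
    """

    sigma: float = DEFAULT_SIGMA
    block: int = DEFAULT_BLOCK
    spacing: int = DEFAULT_SPACING
    n_theta: int = DEFAULT_N_THETA
    eps: float | None = None
    threshold: float | None = None
    threshold_scale: float = 1.0
    reference_speed: float = 10.0
    threshold_factor: float = 0.6
    derivative_method: str = "wrapped_difference"
    center_blocks: bool = True


@dataclass
class MotionMap:
    """Per-block detection results for one frame transition.

    All arrays are indexed ``[k, l]`` (k along x, l along y); ``theta_hat``
    is NaN where no motion was detected.
    """

    pmi: np.ndarray
    detected: np.ndarray
    alpha: np.ndarray
    theta_hat: np.ndarray
    threshold: float
    meta: dict = dc_field(default_factory=dict)

    def direction_vectors(self) -> np.ndarray:
        """Unit vectors (cos theta, sin theta) per block, NaN when undetected."""
        return np.stack([np.cos(self.theta_hat), np.sin(self.theta_hat)], axis=-1)


def _maps_from_fields(den, binning, thetas, rhos, threshold) -> "MotionMap":
    """Build a MotionMap from denoised fields of shape (K, L, M, M)."""
    K, L = den.shape[:2]
    mask = binning.domain.mask
    vals = den[:, :, mask]  # (K, L, npts)
    sums = binning.sums(vals)  # (K, L, n_theta, n_rho)
    prof = np.zeros_like(sums)
    np.divide(np.abs(sums), binning.counts, out=prof, where=binning.counts > 0)
    scores = prof.sum(axis=-1)  # (K, L, n_theta)
    pmi_arr = scores.max(axis=-1)
    amax = scores.argmax(axis=-1)
    detected = pmi_arr > threshold
    alpha = thetas[amax]
    pos = (rhos > 0)[None, None, None, :] & (binning.counts > 0)[None, None, :, :]
    ratio = np.zeros_like(sums)
    np.divide(sums, binning.counts, out=ratio, where=binning.counts > 0)
    pos_sum = np.where(pos, ratio, 0.0).sum(axis=-1)  # (K, L, n_theta)
    s = np.take_along_axis(pos_sum, amax[..., None], axis=-1)[..., 0]
    theta = np.mod(np.pi * (np.sign(s) + 1.0) / 2.0 + alpha, 2.0 * np.pi)
    theta_hat = np.where(detected, theta, np.nan)
    return MotionMap(
        pmi=pmi_arr, detected=detected, alpha=alpha, theta_hat=theta_hat, threshold=float(threshold)
    )


def detect_motion(video: VideoStream, config: DetectorConfig | None = None) -> list[MotionMap]:
    """Run the full phase-based detection pipeline on a video.

    Composes the block STFT, temporal phase derivative, amplitude denoising
    and the Radon/PMI readout; returns one :class:`MotionMap` per frame
    transition (``n_frames - 1`` maps).
    """
    if config is None:
        config = DetectorConfig()
    if video.n_frames < 2:
        raise ValueError("need at least 2 frames to detect motion")
    grid = make_block_grid(video.width, video.height, config.spacing, config.block)
    window = make_gaussian_window(config.sigma, config.block)
    binning = _get_binning(config.block, config.n_theta)

    prev = block_stft(video.frame(0), grid, window, config.center_blocks)
    eps = default_epsilon(prev) if config.eps is None else float(config.eps)
    if config.threshold is None:
        thr = default_threshold(
            config.block, config.n_theta, config.reference_speed, config.threshold_factor
        )
    else:
        thr = float(config.threshold)
    thr *= config.threshold_scale

    maps = []
    for t in range(1, video.n_frames):
        cur = block_stft(video.frame(t), grid, window, config.center_blocks)
        dphi, amp = phase_time_derivative(
            np.stack([prev, cur]), video.dt, method=config.derivative_method
        )
        den = denoise_phase_change(dphi[0], amp[0], eps)
        mm = _maps_from_fields(den, binning, binning.thetas, binning.rhos, thr)
        mm.meta.update({"t": t, "eps": eps})
        maps.append(mm)
        prev = cur
    return maps


def _block_footprint_mask(shape, grid, detected) -> np.ndarray:
    """Union of M x M footprints of detected blocks, as an (H, W) bool mask."""
    H, W = shape
    M = grid.M
    half = M // 2
    mask = np.zeros((H, W), dtype=bool)
    ks, ls = np.nonzero(detected)
    for k, l in zip(ks, ls):
        cx, cy = grid.center(k, l)
        x0, y0 = (cx - 1) - half, (cy - 1) - half
        mask[max(0, y0) : min(H, y0 + M), max(0, x0) : min(W, x0 + M)] = True
    return mask




def _test_patch_motion(prev_frame, cur_frame, center, M, sigma, n_theta, dt,
                       eps_scale=1e-3, center_blocks=True):
    """PMI of a single M x M patch pair centered at a 1-based pixel."""
    from .video_core import extract_block, make_gaussian_window

    win = make_gaussian_window(sigma, M)
    specs = []
    for fr in (prev_frame, cur_frame):
        patch = extract_block(fr, center, M)
        if center_blocks:
            patch = patch - (patch * win.weights).sum() / win.weights.sum()
        patch = patch * win.weights
        specs.append(np.fft.fftshift(np.fft.fft2(np.fft.ifftshift(patch))))
    spectra = np.stack(specs)[:, None, None]  # (2, 1, 1, M, M)
    dphi, amp = phase_time_derivative(spectra, dt)
    eps = eps_scale * float(np.mean(np.abs(specs[0])))
    den = denoise_phase_change(dphi[0, 0, 0], amp[0, 0, 0], eps)
    return pmi(bounded_radon(den, BoundedDomain.for_block(M), n_theta))


def segment_motion(
    video: VideoStream,
    config: DetectorConfig | None = None,
    refine_block: int = 16,
    coarse_scale: float = 2.0,
) -> list[np.ndarray]:
    """Coarse-to-fine motion segmentation; one (H, W) bool mask per transition.

    A raised (salient-object) threshold selects coarse blocks; the coarse
    mask is the union of their M x M footprints. The band of the mask within
    ``refine_block`` pixels of its boundary is then re-tested on a dense
    tiling of ``refine_block``-sized windows; band pixels supported by no
    positive refined test are removed. Refinement is removal-only (the
    refined mask is always a subset of the coarse mask) and never touches
    the mask interior.
    """
    from scipy.ndimage import binary_erosion

    if config is None:
        config = DetectorConfig()
    base_thr = (
        default_threshold(config.block, config.n_theta, config.reference_speed, config.threshold_factor)
        if config.threshold is None
        else float(config.threshold)
    )
    coarse_cfg = DetectorConfig(**{**config.__dict__, "threshold": base_thr * coarse_scale})
    maps = detect_motion(video, coarse_cfg)
    grid = make_block_grid(video.width, video.height, config.spacing, config.block)
    refine_thr = default_threshold(
        refine_block, config.n_theta, config.reference_speed, config.threshold_factor
    ) * coarse_scale
    refine_sigma = config.sigma * refine_block / config.block
    H, W = video.height, video.width
    step = refine_block // 2
    half = refine_block // 2

    masks = []
    for i, mm in enumerate(maps):
        coarse = _block_footprint_mask((H, W), grid, mm.detected)
        if not coarse.any():
            masks.append(coarse)
            continue
        core = binary_erosion(coarse, iterations=refine_block)
        band = coarse & ~core
        keep = np.zeros_like(coarse)
        prev_frame, cur_frame = video.frame(i), video.frame(i + 1)
        for cy0 in range(0, H, step):
            for cx0 in range(0, W, step):
                y0, x0 = cy0 - half, cx0 - half
                sl = (slice(max(0, y0), min(H, y0 + refine_block)),
                      slice(max(0, x0), min(W, x0 + refine_block)))
                if not band[sl].any():
                    continue
                val = _test_patch_motion(
                    prev_frame, cur_frame, (cx0 + 1, cy0 + 1), refine_block,
                    refine_sigma, config.n_theta, video.dt,
                    center_blocks=config.center_blocks,
                )
                if val > refine_thr:
                    keep[sl] = True
        masks.append(core | (band & keep))
    return masks
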