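"""Per-block windowed 2D FFT and the temporal local-phase derivative.

Each block is multiplied by a Gaussian window and Fourier transformed with
the phase referenced to the window center, giving complex local spectra on
the signed frequency grid ``(m*w0, n*w0)``, ``m, n in [-M/2, M/2-1]`` with
``w0 = 2*pi/M``. Spectra are stored as arrays of shape (K, L, M, M) indexed
``[k, l, n_idx, m_idx]`` where ``n_idx = n + M/2`` (y frequency) and
``m_idx = m + M/2`` (x frequency), i.e. DC sits at the middle index M/2.

The temporal phase change is computed either as a wrapped first difference
of the phase or through the quotient form

    dphi/dt = (db/dt * a - da/dt * b) / (a^2 + b^2)

with ``a``, ``b`` the real and imaginary parts of the local spectrum. Both
are exactly invariant to scaling the video by a positive constant.
"""

from __future__ import annotations

import numpy as np

from .video_core import BlockGrid, GaussianWindow, VideoStream, as_frame, extract_block

__all__ = [
    "frequency_grid",
    "block_stft",
    "video_spectra",
    "phase_time_derivative",
    "volterra_phase_derivative",
    "denoise_phase_change",
    "default_epsilon",
    "plane_fit",
    "dump_phase_fields",
]


def frequency_grid(M: int) -> tuple[np.ndarray, np.ndarray]:
    """Signed frequency coordinates (omega_x, omega_y) of an M x M spectrum.

    Returns two (M, M) arrays in rad/pixel, laid out like the spectra:
    axis 0 is the y-frequency index, axis 1 the x-frequency index, both
    ascending from ``-pi`` to ``pi - 2*pi/M`` with DC at index M/2.
    """
    w0 = 2.0 * np.pi / M
    idx = np.arange(M) - M // 2
    omega_x = np.broadcast_to(idx[None, :] * w0, (M, M)).copy()
    omega_y = np.broadcast_to(idx[:, None] * w0, (M, M)).copy()
    return omega_x, omega_y


def block_stft(
    frame: np.ndarray, grid: BlockGrid, window: GaussianWindow, center_blocks: bool = False
) -> np.ndarray:
    """Windowed, center-referenced 2D FFT of every block of a frame.

    Returns a complex array of shape (K, L, M, M); entry ``[k, l, n+M/2,
    m+M/2]`` equals the double sum of ``u(x, y) * w(x - xk, y - yl) *
    exp(-j*(m*w0*(x - xk) + n*w0*(y - yl)))`` over the zero-padded block.

    With ``center_blocks`` the window-weighted mean of each block is
    subtracted before the transform. A constant added to the image leaks
    into every frequency bin through the window's own spectrum; removing
    the weighted mean cancels that leak, making the downstream phase
    pipeline invariant to affine intensity changes on interior blocks.
    """
    if window.M != grid.M:
        raise ValueError(f"window side {window.M} does not match grid block side {grid.M}")
    frame = as_frame(frame)
    if frame.shape != (grid.Py, grid.Px):
        raise ValueError(
            f"frame shape {frame.shape} does not match grid ({grid.Py},{grid.Px})"
        )
    M = grid.M
    wsum = window.weights.sum()
    out = np.empty((grid.K, grid.L, M, M), dtype=np.complex128)
    for k in range(grid.K):
        for l in range(grid.L):
            patch = extract_block(frame, grid.center(k, l), M)
            if center_blocks:
                patch = patch - (patch * window.weights).sum() / wsum
            windowed = patch * window.weights
            # ifftshift puts the center (offset 0) at index 0 so the FFT
            # phase is referenced to the window center; fftshift restores
            # the signed-index ordering with DC at M/2.
            spec = np.fft.fftshift(np.fft.fft2(np.fft.ifftshift(windowed)))
            out[k, l] = spec
    return out


def video_spectra(video: VideoStream, grid: BlockGrid, window: GaussianWindow) -> np.ndarray:
    """Stack of :func:`block_stft` over all frames, shape (T, K, L, M, M)."""
    return np.stack([block_stft(video.frame(t), grid, window) for t in range(video.n_frames)])


def volterra_phase_derivative(a, b, da, db):
    """Phase rate from real/imaginary parts and their time derivatives.

    Computes ``(db*a - da*b) / (a^2 + b^2)`` elementwise and returns 0
    wherever the squared amplitude ``a^2 + b^2`` is exactly zero.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    da = np.asarray(da, dtype=np.float64)
    db = np.asarray(db, dtype=np.float64)
    denom = a * a + b * b
    num = db * a - da * b
    out = np.zeros(np.broadcast_shapes(num.shape, denom.shape), dtype=np.float64)
    np.divide(num, denom, out=out, where=denom > 0)
    return out if out.ndim else float(out)


def phase_time_derivative(
    spectra: np.ndarray, dt: float, method: str = "wrapped_difference"
) -> tuple[np.ndarray, np.ndarray]:
    """Temporal derivative of the local phase, in rad/s.

    Parameters
    ----------
    spectra : complex ndarray, shape (T, ..., M, M)
        Time-ordered local spectra (T >= 2).
    dt : float
        Frame interval in seconds.
    method : {"wrapped_difference", "volterra"}
        ``wrapped_difference`` wraps the first difference of the phase into
        (-pi, pi] before dividing by dt; ``volterra`` uses the quotient form
        with first differences of the real and imaginary parts.

    Returns
    -------
    dphi : ndarray, shape (T-1, ..., M, M)
        Phase change field; 0 wherever the amplitude vanishes.
    amplitude : ndarray, shape (T-1, ..., M, M)
        Companion amplitude |spectrum| at the later frame of each pair,
        used by :func:`denoise_phase_change`.
    """
    spectra = np.asarray(spectra)
    if spectra.ndim < 3 or spectra.shape[0] < 2:
        raise ValueError("need at least 2 time samples of block spectra")
    if dt <= 0:
        raise ValueError("dt must be positive")
    cur, prev = spectra[1:], spectra[:-1]
    amp = np.abs(cur)
    if method == "wrapped_difference":
        # angle(z_t * conj(z_{t-1})) is the phase difference wrapped to
        # (-pi, pi]; identically 0 when either amplitude is 0.
        dphi = np.angle(cur * np.conj(prev)) / dt
        dphi[(amp == 0) | (np.abs(prev) == 0)] = 0.0
    elif method == "volterra":
        a, b = cur.real, cur.imag
        da = (cur.real - prev.real) / dt
        db = (cur.imag - prev.imag) / dt
        dphi = volterra_phase_derivative(a, b, da, db)
    else:
        raise ValueError(f"unknown method {method!r}")
    return dphi, amp


def default_epsilon(spectra_first: np.ndarray, scale: float = 1e-3) -> float:
    """Default denoising constant: ``scale`` times the global mean block
    amplitude of the first frame's spectra."""
    return float(scale * np.mean(np.abs(spectra_first)))


def denoise_phase_change(field: np.ndarray, amplitude: np.ndarray, epsilon: float) -> np.ndarray:
    """Amplitude-weighted attenuation of the phase-change field.

    Each value is multiplied by ``A / ((1/M^2) * sum_grid(A) + epsilon)``
    where the sum runs over the M x M frequency grid of its own block. With
    ``epsilon = 0`` the multiplier is exactly invariant to scaling the video
    by a positive constant.
    """
    if epsilon < 0:
        raise ValueError("epsilon must be nonnegative")
    field = np.asarray(field, dtype=np.float64)
    amplitude = np.asarray(amplitude, dtype=np.float64)
    if field.shape != amplitude.shape:
        raise ValueError("field and amplitude shapes differ")
    mean_amp = amplitude.mean(axis=(-2, -1), keepdims=True)
    denom = mean_amp + epsilon
    mult = np.zeros_like(amplitude)
    np.divide(amplitude, denom, out=mult, where=denom > 0)
    return field * mult


def plane_fit(
    field: np.ndarray,
    weights: np.ndarray | None = None,
    mask: np.ndarray | None = None,
):
    """Least-squares fit of ``-vx*omega_x - vy*omega_y`` to a phase-change field.

    Parameters
    ----------
    field : ndarray, shape (M, M)
        Phase-change values on the frequency grid (rad/s).
    weights : ndarray or None
        Optional nonnegative weights (e.g. local amplitudes).
    mask : ndarray of bool or None
        Optional restriction of the fit to a subset of bins (e.g. the
        circular bounded domain used by the detector).

    Returns
    -------
    (vx, vy, r2) : estimated velocity (px/s) and weighted fraction of the
    field's variance explained by the plane.
    """
    field = np.asarray(field, dtype=np.float64)
    M = field.shape[0]
    wx, wy = frequency_grid(M)
    if mask is None:
        mask = np.ones_like(field, dtype=bool)
    w = np.ones(int(mask.sum())) if weights is None else np.asarray(weights, dtype=np.float64)[mask]
    A = np.stack([-wx[mask], -wy[mask]], axis=1)
    y = field[mask]
    sw = np.sqrt(w)
    coef, *_ = np.linalg.lstsq(A * sw[:, None], y * sw, rcond=None)
    resid = y - A @ coef
    total = np.sum(w * y**2)
    r2 = 1.0 - np.sum(w * resid**2) / total if total > 0 else 0.0
    return float(coef[0]), float(coef[1]), float(r2)


def dump_phase_fields(
    path,
    amplitude: np.ndarray,
    phase: np.ndarray,
    dphase: np.ndarray,
    *,
    sigma: float,
    M: int,
    b0: int,
    frame_rate: float,
) -> None:
    """Dump per-block amplitude/phase/phase-change fields to one HDF5 file."""
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("amplitude", data=amplitude)
        f.create_dataset("phase", data=phase)
        f.create_dataset("dphase", data=dphase)
        f.attrs["sigma"] = sigma
        f.attrs["M"] = M
        f.attrs["b0"] = b0
        f.attrs["frame_rate"] = frame_rate
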