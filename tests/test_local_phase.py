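import numpy as np
import pytest

from phasemotion import local_phase, synthetic, video_core
from phasemotion.local_phase import (
    block_stft,
    default_epsilon,
    denoise_phase_change,
    frequency_grid,
    phase_time_derivative,
    plane_fit,
    volterra_phase_derivative,
)
from phasemotion.radon_detector import BoundedDomain
from phasemotion.video_core import make_block_grid, make_gaussian_window


def stft_direct_sum(frame, grid, window, k, l):
    """Independent oracle: direct double-sum of the windowed transform,
    evaluated term by term (no FFT)."""
    M = grid.M
    cx, cy = grid.center(k, l)
    H, W = frame.shape
    w0 = 2.0 * np.pi / M
    offs = np.arange(-M // 2, M // 2)
    # zero-padded block samples u(x,y) * w(x-xk, y-yl)
    vals = np.zeros((M, M))
    for iy, dy in enumerate(offs):
        for ix, dx in enumerate(offs):
            x, y = (cx - 1) + dx, (cy - 1) + dy
            if 0 <= x < W and 0 <= y < H:
                vals[iy, ix] = frame[y, x] * window.weight_at(dx, dy)
    out = np.empty((M, M), dtype=np.complex128)
    for n in offs:
        for m in offs:
            phases = np.exp(-1j * w0 * (m * offs[None, :] + n * offs[:, None]))
            out[n + M // 2, m + M // 2] = np.sum(vals * phases)
    return out


class TestBlockStft:
    def test_oracle_equivalence_8x8(self, rng):
        grid = make_block_grid(16, 16, 8, 8)
        win = make_gaussian_window(2.0, 8)
        frame = rng.random((16, 16))
        spec = block_stft(frame, grid, win)
        for k, l in [(0, 0), (1, 1)]:
            oracle = stft_direct_sum(frame, grid, win, k, l)
            err = np.max(np.abs(spec[k, l] - oracle)) / np.max(np.abs(oracle))
            assert err < 1e-9

    def test_oracle_equivalence_32x32(self, rng, small_grid, small_window):
        frame = rng.random((64, 64))
        spec = block_stft(frame, small_grid, small_window)
        oracle = stft_direct_sum(frame, small_grid, small_window, 5, 5)
        err = np.max(np.abs(spec[5, 5] - oracle)) / np.max(np.abs(oracle))
        assert err < 1e-9

    def test_constant_frame_spectrum(self, small_grid, small_window):
        c = 0.7
        spec = block_stft(np.full((64, 64), c), small_grid, small_window)[5, 5]
        # spectrum of the (real, point-symmetric) window scaled by c
        win_dft = np.fft.fftshift(np.fft.fft2(np.fft.ifftshift(small_window.weights)))
        np.testing.assert_allclose(spec, c * win_dft, atol=1e-9)
        assert np.max(np.abs(spec.imag)) < 1e-9

    def test_cosine_phase_and_amplitude(self, small_grid, small_window):
        M, m0 = 32, 4
        w0 = 2 * np.pi / M
        cx, cy = small_grid.center(5, 5)
        X = np.arange(64)[None, :].repeat(64, axis=0)
        frame = np.cos(w0 * m0 * (X - (cx - 1)))
        spec = block_stft(frame, small_grid, small_window)[5, 5]
        amp = np.abs(spec)
        # amplitude maximal at (+-m0, 0)
        peak = {tuple(np.unravel_index(np.argmax(amp), amp.shape))}
        assert peak <= {(M // 2, M // 2 + m0), (M // 2, M // 2 - m0)}
        assert amp[M // 2, M // 2 - m0] == pytest.approx(amp[M // 2, M // 2 + m0], rel=1e-9)
        # phase ~ 0 at the cosine's own bin
        assert abs(np.angle(spec[M // 2, M // 2 + m0])) < 1e-6
        oracle = stft_direct_sum(frame, small_grid, small_window, 5, 5)
        assert np.max(np.abs(spec - oracle)) / np.max(np.abs(oracle)) < 1e-9

    def test_shift_property(self, small_grid, small_window):
        M, m0, s = 32, 3, 2
        w0 = 2 * np.pi / M
        X = np.arange(64)[None, :].repeat(64, axis=0)
        f0 = np.cos(w0 * m0 * X)
        f1 = np.cos(w0 * m0 * (X - s))
        b = (M // 2, M // 2 + m0)
        z0 = block_stft(f0, small_grid, small_window)[5, 5][b]
        z1 = block_stft(f1, small_grid, small_window)[5, 5][b]
        dphi = np.angle(z1 * np.conj(z0))
        assert dphi == pytest.approx(-w0 * m0 * s, abs=5e-2)

    def test_size_mismatch_rejected(self, small_grid):
        with pytest.raises(ValueError):
            block_stft(np.zeros((64, 64)), small_grid, make_gaussian_window(4.0, 16))


class TestPhaseTimeDerivative:
    def test_static_video_zero(self, static_video, small_grid, small_window):
        spec = np.stack(
            [block_stft(static_video.frame(t), small_grid, small_window) for t in (0, 1)]
        )
        dphi, _ = phase_time_derivative(spec, static_video.dt)
        np.testing.assert_allclose(dphi, 0.0, atol=1e-10)

    def test_drifting_sinusoid_plane_value(self, small_grid, small_window):
        # full-field sinusoid at bin m0 drifting at v: dphi/dt ~ -omega*v
        M, m0, v, fs = 32, 4, 10.0, 50.0
        w0 = 2 * np.pi / M
        g = synthetic.drifting_grating_video(m0 * w0, v, (64, 64), 0.2, fs)
        spec = np.stack([block_stft(g.frame(t), small_grid, small_window) for t in (3, 4)])
        dphi, _ = phase_time_derivative(spec, 1.0 / fs)
        measured = dphi[0, 5, 5, M // 2, M // 2 + m0]
        assert measured == pytest.approx(-m0 * w0 * v, rel=0.05)

    def test_scale_invariance(self, edge_video, small_grid, small_window):
        spec = np.stack(
            [block_stft(edge_video.frame(t), small_grid, small_window) for t in (4, 5)]
        )
        dphi, _ = phase_time_derivative(spec, edge_video.dt)
        dphi_scaled, _ = phase_time_derivative(3.7 * spec, edge_video.dt)
        # compare modulo the 2*pi/dt wrap: bins whose phase step is exactly
        # +-pi can flip wrap side under scaling (sign of a +-0 imaginary part)
        wrapped = np.angle(np.exp(1j * (dphi_scaled - dphi) * edge_video.dt)) / edge_video.dt
        np.testing.assert_allclose(wrapped, 0.0, atol=1e-8)

    def test_methods_agree_on_smooth_input(self, small_grid, small_window):
        fs = 200.0  # fine dt so the first-order methods agree
        g = synthetic.drifting_grating_video(0.6, 5.0, (64, 64), 0.05, fs)
        spec = np.stack([block_stft(g.frame(t), small_grid, small_window) for t in range(3)])
        d1, _ = phase_time_derivative(spec, 1.0 / fs, method="wrapped_difference")
        d2, _ = phase_time_derivative(spec, 1.0 / fs, method="volterra")
        amp = np.abs(spec[1:])
        strong = amp > 0.05 * amp.max()
        ref = np.abs(d1[strong]).max()
        assert np.max(np.abs(d1[strong] - d2[strong])) < 0.15 * ref

    def test_single_frame_rejected(self, small_grid, small_window, static_video):
        spec = block_stft(static_video.frame(0), small_grid, small_window)[None]
        with pytest.raises(ValueError):
            phase_time_derivative(spec, 0.02)


class TestVolterraForm:
    def test_unit_rotation(self):
        assert volterra_phase_derivative(1.0, 0.0, 0.0, 1.0) == 1.0

    def test_scale_invariance(self, rng):
        a, b, da, db = rng.standard_normal(4)
        lam = 2.5
        v1 = volterra_phase_derivative(a, b, da, db)
        v2 = volterra_phase_derivative(lam * a, lam * b, lam * da, lam * db)
        assert v1 == pytest.approx(v2, rel=1e-12)

    def test_zero_amplitude(self):
        assert volterra_phase_derivative(0.0, 0.0, 1.0, 2.0) == 0.0

    def test_matches_finite_difference_of_phase(self):
        # smooth spiral trajectory; centered differences vs unwrapped atan2
        dt = 1e-3
        t = np.arange(0.0, 1.0, dt)
        r = 1.0 + 0.3 * np.sin(t)
        th = 2.0 * t + 0.5 * np.sin(3.0 * t)
        a, b = r * np.cos(th), r * np.sin(th)
        da = (a[2:] - a[:-2]) / (2 * dt)
        db = (b[2:] - b[:-2]) / (2 * dt)
        vol = volterra_phase_derivative(a[1:-1], b[1:-1], da, db)
        phase = np.unwrap(np.arctan2(b, a))
        fd = (phase[2:] - phase[:-2]) / (2 * dt)
        assert np.max(np.abs(vol - fd)) < 1e-4


class TestDenoise:
    def test_uniform_amplitude_identity(self, rng):
        field = rng.standard_normal((32, 32))
        amp = np.full((32, 32), 3.3)
        np.testing.assert_allclose(denoise_phase_change(field, amp, 0.0), field, rtol=1e-12)

    def test_zero_amplitude_bin_zeroed(self, rng):
        field = rng.standard_normal((8, 8))
        amp = np.ones((8, 8))
        amp[2, 3] = 0.0
        out = denoise_phase_change(field, amp, 0.0)
        assert out[2, 3] == 0.0

    def test_large_epsilon_limit(self, rng):
        field = rng.standard_normal((8, 8))
        amp = np.ones((8, 8))
        out = denoise_phase_change(field, amp, 1e12)
        assert np.max(np.abs(out)) < 1e-10

    def test_negative_epsilon_rejected(self):
        with pytest.raises(ValueError):
            denoise_phase_change(np.zeros((4, 4)), np.ones((4, 4)), -1.0)

    def test_pipeline_contrast_invariance_eps0(self, edge_video, small_grid, small_window):
        lam = 4.2
        out = {}
        for key, scale in (("base", 1.0), ("scaled", lam)):
            spec = np.stack(
                [block_stft(scale * edge_video.frame(t), small_grid, small_window) for t in (4, 5)]
            )
            dphi, amp = phase_time_derivative(spec, edge_video.dt)
            out[key] = denoise_phase_change(dphi, amp, 0.0)
        # identical up to bins sitting exactly on the +-pi wrap boundary,
        # where |value| is preserved but the sign is arbitrary
        same = np.isclose(out["scaled"], out["base"], atol=1e-8)
        flipped = np.isclose(out["scaled"], -out["base"], atol=1e-8)
        assert np.all(same | flipped)
        assert same.mean() > 0.99


class TestPlaneStructure:
    def test_edge_field_is_planar(self, edge_video, small_grid, small_window):
        # blocks the edge crosses: phase-change field explained >= 80% by a
        # plane -vx*wx - vy*wy over the bounded domain
        t = 5
        spec = np.stack(
            [block_stft(edge_video.frame(s), small_grid, small_window) for s in (t, t + 1)]
        )
        dphi, amp = phase_time_derivative(spec, edge_video.dt)
        x_edge = edge_video.meta["origin"][0] + edge_video.meta["edge_offsets"][t]
        dom = BoundedDomain.for_block(32)
        hits = 0
        for k in range(small_grid.K):
            cx, _ = small_grid.center(k, 5)
            if abs((cx - 1) - x_edge) < 8:
                vx, vy, r2 = plane_fit(dphi[0, k, 5], mask=dom.mask)
                assert r2 >= 0.8
                assert vx == pytest.approx(40.0, abs=8.0)
                assert abs(vy) < 8.0
                hits += 1
        assert hits >= 2

    def test_temporal_frequency_tuning(self, small_grid, small_window):
        # denoised response at a fixed bin peaks at the matching grating freq
        M, m0, v, fs = 32, 4, 10.0, 50.0
        w0 = 2 * np.pi / M
        responses = []
        for mg in (2, 3, 4, 5, 6):
            g = synthetic.drifting_grating_video(mg * w0, v, (64, 64), 0.2, fs)
            spec = np.stack([block_stft(g.frame(t), small_grid, small_window) for t in (3, 4)])
            dphi, amp = phase_time_derivative(spec, 1.0 / fs)
            den = denoise_phase_change(dphi[0], amp[0], default_epsilon(spec[0]))
            responses.append(abs(den[5, 5, M // 2, M // 2 + m0]))
        assert int(np.argmax(responses)) == 2  # mg == m0


class TestFrequencyGrid:
    def test_layout(self):
        wx, wy = frequency_grid(8)
        w0 = 2 * np.pi / 8
        assert wx[0, 0] == pytest.approx(-4 * w0)
        assert wx[0, -1] == pytest.approx(3 * w0)
        assert wx[4, 4] == 0.0 and wy[4, 4] == 0.0
        assert wx.shape == (8, 8)


def test_dump_phase_fields(tmp_path, edge_video, small_grid, small_window):
    h5py = pytest.importorskip("h5py")
    spec = np.stack([block_stft(edge_video.frame(t), small_grid, small_window) for t in (0, 1)])
    dphi, amp = phase_time_derivative(spec, edge_video.dt)
    path = tmp_path / "fields.h5"
    local_phase.dump_phase_fields(
        path, np.abs(spec), np.angle(spec), dphi, sigma=4.0, M=32, b0=6, frame_rate=50.0
    )
    with h5py.File(path) as f:
        assert f["dphase"].shape == dphi.shape
        assert f.attrs["M"] == 32
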