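"""Reconstruction of a bandlimited image, up to scale, from local phase.

The image lives in a space of trigonometric polynomials

    u(x, y) = sum_{lx=-Lx..Lx} sum_{ly=-Ly..Ly} c_{lx,ly}
              * exp(j*lx*Omega_x*x/Lx) * exp(j*ly*Omega_y*y/Ly)

of dimension (2*Lx+1)*(2*Ly+1), periodic with Tx = 2*pi*Lx/Omega_x and
Ty = 2*pi*Ly/Omega_y. A bank of Gabor receptive fields (Gaussian window
translated on a b0 lattice, modulated at frequencies m*omega0, n*omega0)
measures local phases phi_{kl,mn}. Each phase yields one linear constraint:
u is orthogonal to w(x-k*b0, y-l*b0) * sin(omega_m*(x-k*b0) +
omega_n*(y-l*b0) + phi_{kl,mn}), so the coefficient vector lies in the null
space of the constraint matrix Phi. With N >= dim - 1 valid measurements in
general position the null space is one-dimensional and u is recovered up to
a scalar; appending a mean-value row pins the scale.

All integrals are evaluated on a uniform quadrature grid over one period
(rectangle rule, which coincides with the trapezoid rule for periodic
integrands); measurement and matrix assembly use the same grid so that the
orthogonality constraints hold to machine precision for consistent data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "TrigPolySpace",
    "GaborBank",
    "PhaseMeasurements",
    "RankDeficiencyError",
    "AmbiguousReconstructionWarning",
    "quadrature_grid",
    "random_real_coefficients",
    "sample_space",
    "measure_local_phase",
    "build_phi",
    "reconstruct_from_phase",
    "snr_db",
]

SNR_CAP_DB = 300.0
VALID_AMP_REL_TOL = 1e-10


class RankDeficiencyError(ValueError):
    """Raised when there are too few measurements for unique reconstruction."""


class AmbiguousReconstructionWarning(UserWarning):
    """Emitted when the two smallest singular values are nearly equal."""


@dataclass(frozen=True)
class TrigPolySpace:
    """Space of 2D trigonometric polynomials of orders (Lx, Ly) and
    bandwidths (Omega_x, Omega_y) rad/unit."""

    Lx: int
    Ly: int
    Omega_x: float
    Omega_y: float

    def __post_init__(self):
        if self.Lx < 1 or self.Ly < 1 or self.Omega_x <= 0 or self.Omega_y <= 0:
            raise ValueError("orders must be >= 1 and bandwidths positive")

    @property
    def dim(self) -> int:
        return (2 * self.Lx + 1) * (2 * self.Ly + 1)

    @property
    def Tx(self) -> float:
        return 2.0 * np.pi * self.Lx / self.Omega_x

    @property
    def Ty(self) -> float:
        return 2.0 * np.pi * self.Ly / self.Omega_y

    def basis_matrix(self, X: np.ndarray, Y: np.ndarray) -> np.ndarray:
        """Basis functions evaluated at points; shape (npoints, dim).

        Column ``q`` (0-based) corresponds to (lx, ly) with
        ``q = (2*Ly + 1)*(lx + Lx) + (ly + Ly)``.
        """
        x = np.asarray(X, dtype=np.float64).ravel()
        y = np.asarray(Y, dtype=np.float64).ravel()
        lx = np.arange(-self.Lx, self.Lx + 1)
        ly = np.arange(-self.Ly, self.Ly + 1)
        ex = np.exp(1j * np.outer(x, lx * self.Omega_x / self.Lx))  # (n, 2Lx+1)
        ey = np.exp(1j * np.outer(y, ly * self.Omega_y / self.Ly))  # (n, 2Ly+1)
        return (ex[:, :, None] * ey[:, None, :]).reshape(x.size, self.dim)

    def coeff_vector(self, coeffs: np.ndarray) -> np.ndarray:
        """Flatten a (2Lx+1, 2Ly+1) coefficient array in column order q."""
        coeffs = np.asarray(coeffs)
        if coeffs.shape != (2 * self.Lx + 1, 2 * self.Ly + 1):
            raise ValueError("coefficient array has wrong shape")
        return coeffs.reshape(self.dim)

    def coeff_array(self, vector: np.ndarray) -> np.ndarray:
        return np.asarray(vector).reshape(2 * self.Lx + 1, 2 * self.Ly + 1)


def quadrature_grid(space: TrigPolySpace, oversample: float = 1.0):
    """Uniform quadrature grid over one period [0, Tx) x [0, Ty).

    The grid resolves at least 4 samples per shortest period of the
    integrands (basis frequency up to Omega plus modulation up to Omega,
    i.e. combined spatial frequency up to 2*Omega).

    Returns (X, Y, dA) with X, Y of shape (ny, nx).
    """
    nx = int(np.ceil(8 * space.Lx * oversample)) + 8
    ny = int(np.ceil(8 * space.Ly * oversample)) + 8
    xs = np.arange(nx) * (space.Tx / nx)
    ys = np.arange(ny) * (space.Ty / ny)
    X, Y = np.meshgrid(xs, ys)
    dA = (space.Tx / nx) * (space.Ty / ny)
    return X, Y, dA


def random_real_coefficients(space: TrigPolySpace, rng: np.random.Generator) -> np.ndarray:
    """Random conjugate-symmetric coefficients (real image), shape
    (2Lx+1, 2Ly+1)."""
    nLx, nLy = 2 * space.Lx + 1, 2 * space.Ly + 1
    c = (rng.standard_normal((nLx, nLy)) + 1j * rng.standard_normal((nLx, nLy))) / np.sqrt(2)
    sym = 0.5 * (c + np.conj(c[::-1, ::-1]))  # c_{-lx,-ly} = conj(c_{lx,ly})
    return sym


def sample_space(space: TrigPolySpace, coeffs: np.ndarray, X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Evaluate the trigonometric polynomial at the given points.

    Returns a real array when the coefficients are conjugate symmetric
    (up to round-off), otherwise complex.
    """
    E = space.basis_matrix(X, Y)
    vals = E @ space.coeff_vector(coeffs)
    vals = vals.reshape(np.shape(X))
    if np.max(np.abs(vals.imag)) < 1e-9 * max(np.max(np.abs(vals.real)), 1e-30):
        return vals.real.copy()
    return vals


def _periodized_gaussian(d: np.ndarray, T: float, sigma: float, n_images: int = 3) -> np.ndarray:
    """Sum of Gaussian images exp(-(d + k*T)^2 / (2*sigma^2)), k in [-n, n]."""
    out = np.zeros_like(np.asarray(d, dtype=np.float64))
    for k in range(-n_images, n_images + 1):
        out += np.exp(-((d + k * T) ** 2) / (2.0 * sigma**2))
    return out


@dataclass(frozen=True)
class GaborBank:
    """Bank of Gabor receptive fields on a (k*b0, l*b0) x (m*w0, n*w0) lattice.

    The index set is all (k, l, m, n) with 0 <= k*b0 <= Tx, 0 <= l*b0 <= Ty,
    -Omega_x <= m*omega0 <= Omega_x, -Omega_y <= n*omega0 <= Omega_y.
    Windows are Gaussians of width sigma, wrapped periodically over the
    fundamental domain.
    """

    space: TrigPolySpace
    b0: float
    omega0: float
    sigma: float

    def __post_init__(self):
        if self.b0 <= 0 or self.omega0 <= 0 or self.sigma <= 0:
            raise ValueError("b0, omega0 and sigma must be positive")
        # The quadrature folds the plane onto one period, which represents
        # the modulated windows exactly only when each modulation frequency
        # advances by a whole number of cycles per period, i.e. omega0 on
        # the space's frequency lattice (multiples of Omega/L).
        for om, T in ((self.omega0, self.space.Tx), (self.omega0, self.space.Ty)):
            cycles = om * T / (2.0 * np.pi)
            if abs(cycles - round(cycles)) > 1e-9:
                warnings.warn(
                    "omega0 is incommensurate with the space's period; "
                    "folded quadrature of the Gabor responses is inexact",
                    UserWarning,
                    stacklevel=3,
                )
                break

    @property
    def index_set(self) -> np.ndarray:
        """(N, 4) integer array of (k, l, m, n)."""
        kmax = int(np.floor(self.space.Tx / self.b0 + 1e-12))
        lmax = int(np.floor(self.space.Ty / self.b0 + 1e-12))
        mmax = int(np.floor(self.space.Omega_x / self.omega0 + 1e-12))
        nmax = int(np.floor(self.space.Omega_y / self.omega0 + 1e-12))
        idx = [
            (k, l, m, n)
            for k in range(kmax + 1)
            for l in range(lmax + 1)
            for m in range(-mmax, mmax + 1)
            for n in range(-nmax, nmax + 1)
        ]
        return np.array(idx, dtype=np.int64)

    def window(self, k: int, l: int, X: np.ndarray, Y: np.ndarray) -> np.ndarray:
        """Periodized Gaussian window centered at (k*b0, l*b0).

        Periodization sums wrapped images of the Gaussian (rather than using
        the nearest image only), keeping the window smooth across the period
        seam so the trapezoid quadrature retains spectral accuracy.
        """
        Tx, Ty = self.space.Tx, self.space.Ty
        wx = _periodized_gaussian(X - k * self.b0, Tx, self.sigma)
        wy = _periodized_gaussian(Y - l * self.b0, Ty, self.sigma)
        return wx * wy


@dataclass
class PhaseMeasurements:
    """Local phases phi in [0, 2*pi) per (k, l, m, n) receptive field.

    ``amplitude`` is retained only to set validity flags; reconstruction
    never reads it (phase-only contract).
    """

    indices: np.ndarray   # (N, 4) int: k, l, m, n
    phi: np.ndarray       # (N,) float in [0, 2*pi)
    amplitude: np.ndarray  # (N,) float >= 0
    valid: np.ndarray     # (N,) bool

    @property
    def n_valid(self) -> int:
        return int(np.count_nonzero(self.valid))

    def subset(self, sel) -> "PhaseMeasurements":
        return PhaseMeasurements(
            indices=self.indices[sel],
            phi=self.phi[sel],
            amplitude=self.amplitude[sel],
            valid=self.valid[sel],
        )


def measure_local_phase(u: np.ndarray, bank: GaborBank, grid=None) -> PhaseMeasurements:
    """Local phases of an image sampled on the quadrature grid.

    ``u`` must be sampled on ``grid`` (defaults to ``quadrature_grid`` of the
    bank's space). Each measurement is the argument of the discretized
    integral of u against the Gabor receptive field; measurements whose
    amplitude falls below ``1e-10`` of the maximum are flagged invalid.
    """
    if grid is None:
        grid = quadrature_grid(bank.space)
    X, Y, dA = grid
    u = np.asarray(u, dtype=np.float64)
    if u.shape != X.shape:
        raise ValueError("image must be sampled on the quadrature grid")
    idx = bank.index_set
    N = idx.shape[0]
    phi = np.empty(N)
    amp = np.empty(N)
    # group by window position; frequencies separate over x and y
    ms = np.unique(idx[:, 2])
    ns = np.unique(idx[:, 3])
    xs, ys = X[0, :], Y[:, 0]
    pos_pairs = np.unique(idx[:, :2], axis=0)
    lookup = {}
    for k, l in pos_pairs:
        w = bank.window(k, l, X, Y)
        B = u * w * dA
        Ey = np.exp(-1j * bank.omega0 * np.outer(ns, ys - l * bank.b0))  # (n_n, ny)
        Ex = np.exp(-1j * bank.omega0 * np.outer(xs - k * bank.b0, ms))  # (nx, n_m)
        resp = Ey @ B @ Ex  # (n_n, n_m)
        lookup[(k, l)] = resp
    m_pos = {m: i for i, m in enumerate(ms)}
    n_pos = {n: i for i, n in enumerate(ns)}
    for p, (k, l, m, n) in enumerate(idx):
        z = lookup[(k, l)][n_pos[n], m_pos[m]]
        amp[p] = np.abs(z)
        phi[p] = np.mod(np.angle(z), 2.0 * np.pi)
    amax = amp.max() if amp.size else 0.0
    if amax == 0.0:
        valid = np.zeros(N, dtype=bool)
    else:
        valid = amp >= VALID_AMP_REL_TOL * amax
    return PhaseMeasurements(indices=idx, phi=phi, amplitude=amp, valid=valid)


def build_phi(measurements: PhaseMeasurements, space: TrigPolySpace, bank: GaborBank, grid=None) -> np.ndarray:
    """Assemble the constraint matrix Phi, one row per valid measurement.

    Entry (p, q) is the quadrature of ``w(x - k*b0, y - l*b0) *
    sin(m*w0*(x - k*b0) + n*w0*(y - l*b0) + phi_p) * e_q(x, y)`` over one
    period; the true coefficient vector satisfies ``Phi @ c = 0``.
    """
    if grid is None:
        grid = quadrature_grid(space)
    X, Y, dA = grid
    sel = np.nonzero(measurements.valid)[0]
    if sel.size == 0:
        raise ValueError("no valid phase measurements")
    E = space.basis_matrix(X, Y)  # (G, dim)
    G = X.size
    F = np.empty((sel.size, G))
    for r, p in enumerate(sel):
        k, l, m, n = measurements.indices[p]
        w = bank.window(k, l, X, Y)
        psi = (
            m * bank.omega0 * (X - k * bank.b0)
            + n * bank.omega0 * (Y - l * bank.b0)
            + measurements.phi[p]
        )
        F[r] = (w * np.sin(psi)).ravel()
    return (F * dA) @ E


def reconstruct_from_phase(
    measurements: PhaseMeasurements,
    space: TrigPolySpace,
    bank: GaborBank,
    grid=None,
    add_mean_row: bool = False,
    mean_value: float | None = None,
    gap_rel_tol: float = 1e-6,
):
    """Recover the coefficient array from phase measurements alone.

    Without ``add_mean_row`` the smallest right singular vector of Phi is
    returned (reconstruction up to a complex scale, normalized to unit
    energy). With ``add_mean_row`` the mean-value constraint
    ``integral(u) = mean_value`` is appended and the least-squares solution
    of the augmented system is returned.

    Raises :class:`RankDeficiencyError` when the number of valid
    measurements is below ``dim - 1``; warns with
    :class:`AmbiguousReconstructionWarning` when the two smallest singular
    values are nearly equal (ill-determined null direction).
    """
    n_valid = measurements.n_valid
    bound = space.dim - 1
    if n_valid < bound:
        raise RankDeficiencyError(
            f"{n_valid} valid phase measurements, but at least dim - 1 = "
            f"{bound} are necessary for reconstruction up to scale"
        )
    if grid is None:
        grid = quadrature_grid(space)
    Phi = build_phi(measurements, space, bank, grid)
    if add_mean_row:
        X, Y, dA = grid
        E = space.basis_matrix(X, Y)
        row = (np.ones(X.size) * dA) @ E
        if mean_value is None:
            raise ValueError("mean_value required when add_mean_row is set")
        A = np.vstack([Phi, row[None, :]])
        b = np.zeros(A.shape[0], dtype=np.complex128)
        b[-1] = mean_value
        c, *_ = np.linalg.lstsq(A, b, rcond=None)
        return space.coeff_array(c)
    _, s, Vh = np.linalg.svd(Phi, full_matrices=False)
    if s.size >= 2 and (s[-2] - s[-1]) < gap_rel_tol * s[0]:
        warnings.warn(
            "null direction of Phi is numerically ambiguous "
            f"(two smallest singular values {s[-1]:.3e}, {s[-2]:.3e})",
            AmbiguousReconstructionWarning,
        )
    c = np.conj(Vh[-1])
    c = c / np.linalg.norm(c)
    return space.coeff_array(c)


def snr_db(original: np.ndarray, reconstructed: np.ndarray) -> float:
    """SNR after optimal least-squares scaling of the reconstruction.

    Applies the scale ``lambda* = <u_hat, u> / ||u_hat||^2`` and returns
    ``10*log10(||u||^2 / ||u - lambda* u_hat||^2)``, capped at 300 dB.
    """
    u = np.asarray(original).ravel()
    v = np.asarray(reconstructed).ravel()
    if u.shape != v.shape:
        raise ValueError("images must share the sampling grid")
    energy = np.vdot(u, u).real
    if energy == 0:
        raise ValueError("original image is identically zero")
    vv = np.vdot(v, v).real
    lam = np.vdot(v, u) / vv if vv > 0 else 0.0
    err = np.vdot(u - lam * v, u - lam * v).real
    if err <= 0 or energy / err > 10 ** (SNR_CAP_DB / 10.0):
        return SNR_CAP_DB
    return float(10.0 * np.log10(energy / err))
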