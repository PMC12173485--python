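"""Two-dimensional synthetic (kinematic) turbulent flow and analytic test flows.

The velocity field mimics homogeneous, isotropic turbulence at the dissipative
scale: a sea of vortices of roughly fixed size ``lambda_f`` rotating with mean
absolute speed ``uf``, each vortex fluctuating, deforming and dying on a
timescale ``tau_f``.  It is built from a random-Fourier-mode stream function

    psi(x, t) = sum_k A_k(t) exp(i k.x) + c.c.

over integer wavevectors on a thin spectral shell ``|k| in [k0-hw, k0+hw]``,
so the dominant wavelength ``2*pi/k0`` matches the vortex size in the periodic
``L x L`` box.  Each complex amplitude follows an independent mean-reverting
(Ornstein-Uhlenbeck) process with correlation time ``tau_f``, advanced with the
exact-in-distribution update so the temporal statistics carry no step-size
bias.  Velocities derive from the stream function (u = dpsi/dy, v = -dpsi/dx),
which makes the field exactly incompressible; vorticity and rate of strain are
obtained by exact spectral differentiation.

The Kubo number Ku = tau_f / (lambda_f/uf) measures flow unsteadiness relative
to the eddy turnover time; the default non-dimensionalization (uf=1,
lambda_f=1, tau_f=2*pi, L=2*pi) gives Ku = 2*pi.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np

TWO_PI = 2.0 * math.pi

__all__ = [
    "FlowParams",
    "FlowState",
    "FlowSample",
    "AnalyticFlow",
    "GriddedFlow",
    "init_flow",
    "advance_flow",
    "sample_flow",
    "flow_grids",
    "longitudinal_correlation_length",
]


# ---------------------------------------------------------------------------
# parameters and state
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FlowParams:
    """Parameters of the synthetic turbulent flow (flow units).

    Attributes
    ----------
    uf : float
        Spatial-mean absolute velocity of the field.
    lambda_f : float
        Vortex size; the dominant stream-function wavelength is matched to it.
    tau_f : float
        Decorrelation (vortex lifetime) time. ``numpy.inf`` freezes the flow.
    L : float
        Side of the periodic square domain.
    n_modes : int
        Number of Fourier modes kept (capped at the size of the spectral
        shell; the default covers the whole shell for k0=6, k_halfwidth=1).
    k0 : int
        Peak integer wavenumber; the dominant wavelength is ``L/k0``.
    k_halfwidth : float
        Half-width of the spectral shell ``|k| in [k0-hw, k0+hw]``.
    seed : int
        Seed of the flow's private random stream.
    """

    uf: float = 1.0
    lambda_f: float = 1.0
    tau_f: float = TWO_PI
    L: float = TWO_PI
    n_modes: int = 40
    k0: int = 2
    k_halfwidth: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.uf > 0 and self.lambda_f > 0 and self.L > 0):
            raise ValueError("uf, lambda_f and L must be positive")
        if not self.tau_f > 0:
            raise ValueError("tau_f must be positive (numpy.inf allowed)")
        if self.k0 < 1:
            raise ValueError("k0 must be >= 1")
        if self.n_modes < 2:
            raise ValueError("n_modes must be >= 2")

    @property
    def eddy_turnover(self) -> float:
        """tf = lambda_f / uf, the time a fluid element needs to cross a vortex."""
        return self.lambda_f / self.uf

    @property
    def kubo(self) -> float:
        """Kubo number Ku = tau_f * uf / lambda_f."""
        return self.tau_f * self.uf / self.lambda_f


def _shell_wavevectors(k0: int, halfwidth: float) -> np.ndarray:
    """Integer wavevectors on the half-plane shell |n| in [k0-hw, k0+hw].

    Only one member of each (n, -n) pair is kept; the conjugate partner is
    implicit in the `+ c.c.` of the stream-function sum, which guarantees
    real-valued physical fields (Hermitian symmetry).
    """
    nmax = int(math.ceil(k0 + halfwidth))
    lo, hi = k0 - halfwidth, k0 + halfwidth
    out = []
    for nx in range(-nmax, nmax + 1):
        for ny in range(0, nmax + 1):
            if ny == 0 and nx <= 0:
                continue  # keep the kx>0 half of the ky=0 axis
            if lo <= math.hypot(nx, ny) <= hi:
                out.append((nx, ny))
    return np.asarray(out, dtype=np.int64).reshape(-1, 2)


@dataclass
class FlowState:
    """Spectral state of the synthetic flow.

    ``amplitudes[m]`` multiplies ``exp(i k_m . x)`` in the stream function; the
    complex conjugate partner is implicit.  ``mode_var`` is the stationary
    value of ``E|A|^2`` targeted by the mean-reverting temporal process.
    """

    params: FlowParams
    wavevectors: np.ndarray  # (M, 2) integer lattice vectors
    amplitudes: np.ndarray  # (M,) complex
    mode_var: float
    time: float
    rng: np.random.Generator

    periodic = True

    @property
    def L(self) -> float:
        return self.params.L

    @property
    def k(self) -> np.ndarray:
        """Physical wavevectors (M, 2)."""
        return self.wavevectors * (TWO_PI / self.params.L)

    def sample_fields(self, positions: np.ndarray):
        """Velocity, vorticity and strain at arbitrary points (exact spectral sum).

        Returns ``(u, omega, exx, exy)`` with shapes (N,2), (N,), (N,), (N,);
        the rate-of-strain tensor is [[exx, exy], [exy, -exx]] (traceless).
        """
        pos = np.atleast_2d(np.asarray(positions, dtype=float))
        if pos.size == 0:
            z = np.zeros((0,))
            return np.zeros((0, 2)), z, z, z
        k = self.k
        phase = pos @ k.T  # (N, M)
        z = np.exp(1j * phase) * self.amplitudes
        zr, zi = z.real, z.imag
        kx, ky = k[:, 0], k[:, 1]
        u = np.empty((pos.shape[0], 2))
        u[:, 0] = -2.0 * (zi @ ky)
        u[:, 1] = 2.0 * (zi @ kx)
        omega = 2.0 * (zr @ (kx * kx + ky * ky))
        exx = -2.0 * (zr @ (kx * ky))
        exy = zr @ (kx * kx - ky * ky)
        return u, omega, exx, exy

    def copy(self) -> "FlowState":
        """Independent deep copy, including the random stream position."""
        rng = np.random.default_rng()
        rng.bit_generator.state = self.rng.bit_generator.state
        return FlowState(
            params=self.params,
            wavevectors=self.wavevectors.copy(),
            amplitudes=self.amplitudes.copy(),
            mode_var=self.mode_var,
            time=self.time,
            rng=rng,
        )


@dataclass
class FlowSample:
    """Velocity ``u``, scalar vorticity ``omega`` and symmetric traceless
    rate-of-strain tensor ``E`` at one or more points."""

    u: np.ndarray  # (N, 2)
    omega: np.ndarray  # (N,)
    E: np.ndarray  # (N, 2, 2)


# ---------------------------------------------------------------------------
# construction and temporal evolution
# ---------------------------------------------------------------------------


def init_flow(params: FlowParams) -> FlowState:
    """Draw a flow realization from the stationary amplitude distribution.

    Amplitudes are i.i.d. complex Gaussians over the spectral shell, then
    rescaled so the instantaneous spatial-mean speed on a 64x64 grid equals
    ``uf`` exactly; the stationary variance of the temporal process is set to
    the rescaled value, so later evolution preserves the normalization
    statistically (not instantaneously).  Deterministic given ``params.seed``.
    """
    rng = np.random.default_rng(params.seed)
    shell = _shell_wavevectors(params.k0, params.k_halfwidth)
    if len(shell) == 0:
        raise ValueError(
            f"no integer wavevectors in shell |k| in "
            f"[{params.k0 - params.k_halfwidth}, {params.k0 + params.k_halfwidth}]"
        )
    if params.n_modes < len(shell):
        idx = np.sort(rng.choice(len(shell), size=params.n_modes, replace=False))
        shell = shell[idx]
    m = len(shell)
    amps = (rng.standard_normal(m) + 1j * rng.standard_normal(m)) / math.sqrt(2.0)
    state = FlowState(
        params=params,
        wavevectors=shell,
        amplitudes=amps,
        mode_var=1.0,
        time=0.0,
        rng=rng,
    )
    grids = flow_grids(state, 64)
    mean_speed = float(np.mean(np.hypot(grids[0], grids[1])))
    scale = params.uf / mean_speed
    state.amplitudes = amps * scale
    # stationary target of the temporal process: the realization's own
    # post-rescale variance (using the ensemble value scale^2 instead would
    # bias the long-time energy upward by E[1/V_emp] - 1, Jensen's inequality)
    state.mode_var = float(np.mean(np.abs(state.amplitudes) ** 2))
    return state


def advance_flow(state: FlowState, dt: float) -> FlowState:
    """Advance the mode amplitudes by one exact mean-reverting step.

    Each amplitude relaxes as ``A -> a A + noise`` with ``a = exp(-dt/tau_f)``
    and noise variance ``(1 - a^2) * mode_var``: exact in distribution for any
    ``dt``, stationary by construction.  The state is updated in place and
    returned.  ``tau_f = inf`` gives a frozen flow.
    """
    if not dt > 0:
        raise ValueError("dt must be positive")
    tau = state.params.tau_f
    if math.isinf(tau):
        state.time += dt
        return state
    a = math.exp(-dt / tau)
    m = len(state.amplitudes)
    sd = math.sqrt(state.mode_var * (1.0 - a * a) / 2.0)
    noise = sd * (state.rng.standard_normal(m) + 1j * state.rng.standard_normal(m))
    state.amplitudes = a * state.amplitudes + noise
    state.time += dt
    return state


def sample_flow(flow, positions) -> FlowSample:
    """Sample velocity, vorticity and full strain tensor at given points.

    Works for any flow-like object exposing ``sample_fields`` (synthetic
    spectral state, gridded sampler, or analytic flow).  Positions outside the
    periodic domain are wrapped by the sampler where applicable.
    """
    u, omega, exx, exy = flow.sample_fields(positions)
    n = len(omega)
    E = np.empty((n, 2, 2))
    E[:, 0, 0] = exx
    E[:, 0, 1] = exy
    E[:, 1, 0] = exy
    E[:, 1, 1] = -exx
    return FlowSample(u=u, omega=omega, E=E)


# ---------------------------------------------------------------------------
# gridded synthesis (for large populations and the scalar field)
# ---------------------------------------------------------------------------


def flow_grids(state: FlowState, n: int) -> np.ndarray:
    """Synthesize (ux, uy, omega, exx, exy) on an n x n periodic grid via FFT.

    Grid nodes sit at ``x_i = i * L / n``; values are spectrally exact there.
    Returns an array of shape (5, n, n) indexed ``[field, ix, iy]``.
    """
    kfac = TWO_PI / state.params.L
    kx = state.wavevectors[:, 0] * kfac
    ky = state.wavevectors[:, 1] * kfac
    A = state.amplitudes
    coeffs = np.stack(
        [
            1j * ky * A,  # ux = dpsi/dy
            -1j * kx * A,  # uy = -dpsi/dx
            (kx * kx + ky * ky) * A,  # omega = -laplacian(psi)
            -kx * ky * A,  # exx = d(ux)/dx
            0.5 * (kx * kx - ky * ky) * A,  # exy
        ]
    )
    spec = np.zeros((5, n, n), dtype=complex)
    ix = state.wavevectors[:, 0] % n
    iy = state.wavevectors[:, 1] % n
    jx = (-state.wavevectors[:, 0]) % n
    jy = (-state.wavevectors[:, 1]) % n
    for f in range(5):
        np.add.at(spec[f], (ix, iy), coeffs[f])
        np.add.at(spec[f], (jx, jy), np.conj(coeffs[f]))
    # Hermitian spectra give real fields, so two fields ride one complex FFT
    p01 = np.fft.ifft2(spec[0] + 1j * spec[1])
    p23 = np.fft.ifft2(spec[2] + 1j * spec[3])
    p4 = np.fft.ifft2(spec[4])
    out = np.empty((5, n, n))
    out[0], out[1] = p01.real, p01.imag
    out[2], out[3] = p23.real, p23.imag
    out[4] = p4.real
    out *= n * n
    return out


def _bilinear_stack(grids: np.ndarray, pos: np.ndarray, L: float) -> np.ndarray:
    """Periodic bilinear interpolation of stacked (F, n, n) grids at (N, 2) points.

    Hot path of the simulation: gathers use flattened indices, and the
    periodic neighbour wrap avoids a second modulo.
    """
    n = grids.shape[-1]
    flat = grids.reshape(grids.shape[0], -1)
    sx = pos[:, 0] * (n / L)
    sy = pos[:, 1] * (n / L)
    ix0 = np.floor(sx).astype(np.int64)
    iy0 = np.floor(sy).astype(np.int64)
    fx = sx - ix0
    fy = sy - iy0
    ix0 %= n
    iy0 %= n
    ix1 = ix0 + 1
    ix1[ix1 == n] = 0
    iy1 = iy0 + 1
    iy1[iy1 == n] = 0
    b00 = ix0 * n + iy0
    b10 = ix1 * n + iy0
    g0 = np.take(flat, b00, axis=1) * (1.0 - fy) + np.take(flat, b00 + (iy1 - iy0), axis=1) * fy
    g1 = np.take(flat, b10, axis=1) * (1.0 - fy) + np.take(flat, b10 + (iy1 - iy0), axis=1) * fy
    return g0 * (1.0 - fx) + g1 * fx


try:  # fused single-pass kernel; the numpy path above is the exact fallback
    import numba as _numba

    @_numba.njit(cache=False)
    def _bilinear_stack_jit(grids, x, y, L):  # pragma: no cover - numba path
        F, n, _ = grids.shape
        N = x.shape[0]
        out = np.empty((F, N))
        fac = n / L
        for i in range(N):
            sx = x[i] * fac
            sy = y[i] * fac
            ix0 = int(np.floor(sx))
            iy0 = int(np.floor(sy))
            fx = sx - ix0
            fy = sy - iy0
            ix0 %= n
            iy0 %= n
            ix1 = ix0 + 1
            if ix1 == n:
                ix1 = 0
            iy1 = iy0 + 1
            if iy1 == n:
                iy1 = 0
            w00 = (1.0 - fx) * (1.0 - fy)
            w10 = fx * (1.0 - fy)
            w01 = (1.0 - fx) * fy
            w11 = fx * fy
            for f in range(F):
                out[f, i] = (grids[f, ix0, iy0] * w00 + grids[f, ix1, iy0] * w10
                             + grids[f, ix0, iy1] * w01 + grids[f, ix1, iy1] * w11)
        return out

except ImportError:  # pragma: no cover
    _bilinear_stack_jit = None


class GriddedFlow:
    """Fast sampler for a synthetic flow: spectral synthesis on a grid plus
    periodic bilinear interpolation.

    Spectrally exact at grid nodes; between nodes the interpolation error is
    O((k_max h)^2) of the field amplitude (about 0.4% at the default n=256
    for k0=6).  The cache refreshes automatically whenever the underlying
    ``FlowState`` time has advanced, so one synthesis serves all substeps of
    an integrator step.
    """

    periodic = True

    def __init__(self, state: FlowState, n: int = 256):
        self.state = state
        self.n = int(n)
        self._cached_time: float | None = None
        self._grids: np.ndarray | None = None

    @property
    def L(self) -> float:
        return self.state.params.L

    def refresh(self) -> None:
        self._grids = flow_grids(self.state, self.n)
        self._cached_time = self.state.time

    def sample_fields(self, positions):
        if self._cached_time != self.state.time:
            self.refresh()
        pos = np.atleast_2d(np.asarray(positions, dtype=float))
        if pos.size == 0:
            z = np.zeros((0,))
            return np.zeros((0, 2)), z, z, z
        if _bilinear_stack_jit is not None:
            vals = _bilinear_stack_jit(self._grids,
                                       np.ascontiguousarray(pos[:, 0]),
                                       np.ascontiguousarray(pos[:, 1]), self.L)
        else:
            vals = _bilinear_stack(self._grids, pos % self.L, self.L)
        u = np.stack([vals[0], vals[1]], axis=1)
        return u, vals[2], vals[3], vals[4]

    def velocity_grids(self):
        """Cached (ux, uy) node values, refreshing if needed."""
        if self._cached_time != self.state.time:
            self.refresh()
        return self._grids[0], self._grids[1]


# ---------------------------------------------------------------------------
# analytic flows (closed-form fixtures)
# ---------------------------------------------------------------------------


class AnalyticFlow:
    """Closed-form flows used as exact fixtures: solid-body rotation, simple
    shear, steady cellular flow, and quiescent fluid.

    These are globally defined (no periodic wrapping), and return exact u,
    omega and E at any point.
    """

    periodic = False
    L = None

    def __init__(self, kind: str, **params):
        if kind not in {"solid_body", "simple_shear", "cellular", "quiescent"}:
            raise ValueError(f"unknown analytic flow kind: {kind!r}")
        self.kind = kind
        self.params = params

    @classmethod
    def solid_body(cls, Omega: float, center=(0.0, 0.0)) -> "AnalyticFlow":
        """Rigid rotation at angular rate Omega about ``center``; omega = 2*Omega, E = 0."""
        return cls("solid_body", Omega=Omega, center=tuple(center))

    @classmethod
    def simple_shear(cls, gamma: float) -> "AnalyticFlow":
        """u = (gamma*y, 0); omega = -gamma, E_xy = gamma/2."""
        return cls("simple_shear", gamma=gamma)

    @classmethod
    def cellular(cls, amplitude: float = 1.0, wavenumber: float = 1.0) -> "AnalyticFlow":
        """Steady array of counter-rotating cells, psi = (U/k) sin(kx) sin(ky)."""
        return cls("cellular", amplitude=amplitude, wavenumber=wavenumber)

    @classmethod
    def quiescent(cls) -> "AnalyticFlow":
        return cls("quiescent")

    def sample_fields(self, positions):
        pos = np.atleast_2d(np.asarray(positions, dtype=float))
        npts = pos.shape[0]
        u = np.zeros((npts, 2))
        omega = np.zeros(npts)
        exx = np.zeros(npts)
        exy = np.zeros(npts)
        if self.kind == "solid_body":
            Om = self.params["Omega"]
            cx, cy = self.params["center"]
            u[:, 0] = -Om * (pos[:, 1] - cy)
            u[:, 1] = Om * (pos[:, 0] - cx)
            omega[:] = 2.0 * Om
        elif self.kind == "simple_shear":
            g = self.params["gamma"]
            u[:, 0] = g * pos[:, 1]
            omega[:] = -g
            exy[:] = 0.5 * g
        elif self.kind == "cellular":
            U = self.params["amplitude"]
            k = self.params["wavenumber"]
            sx, cxx = np.sin(k * pos[:, 0]), np.cos(k * pos[:, 0])
            sy, cyy = np.sin(k * pos[:, 1]), np.cos(k * pos[:, 1])
            u[:, 0] = U * sx * cyy
            u[:, 1] = -U * cxx * sy
            omega[:] = 2.0 * U * k * sx * sy
            exx[:] = U * k * cxx * cyy
        return u, omega, exx, exy


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------


def longitudinal_correlation_length(state: FlowState, n: int = 256) -> float:
    """e-folding radius of the longitudinal velocity correlation function.

    Computed on an n x n grid by FFT (Wiener-Khinchin): R_L(r) correlates a
    velocity component with itself at separations along its own direction
    (ux along x and uy along y, averaged).  The radius where the normalized
    correlation first falls below 1/e measures the vortex size and serves as
    the scale-match diagnostic against ``lambda_f``.
    """
    grids = flow_grids(state, n)
    ux, uy = grids[0], grids[1]
    cx = np.fft.ifft(np.abs(np.fft.fft(ux, axis=0)) ** 2, axis=0).real.mean(axis=1)
    cy = np.fft.ifft(np.abs(np.fft.fft(uy, axis=1)) ** 2, axis=1).real.mean(axis=0)
    corr = (cx / cx[0] + cy / cy[0]) / 2.0
    h = state.params.L / n
    thresh = 1.0 / math.e
    below = np.nonzero(corr[: n // 2] <= thresh)[0]
    if len(below) == 0:
        return math.inf
    j = below[0]
    # linear interpolation of the threshold crossing between samples j-1 and j
    c0, c1 = corr[j - 1], corr[j]
    frac = (c0 - thresh) / (c0 - c1)
    return float((j - 1 + frac) * h)
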