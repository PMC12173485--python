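"""Self-propelled ellipsoidal swimmers in a prescribed 2D flow.

During runs a swimmer translates with the total velocity u(x,t) + us*p and its
orientation p obeys Jeffery/Bretherton dynamics,

    dp/dt = (1/2) omega x p + alpha (I - pp) E p,

with scalar 2D vorticity omega and traceless symmetric rate of strain E.  The
shape enters through the Bretherton parameter alpha = (r^2-1)/(r^2+1) in
[0, 1): spheres (alpha=0) are rotated by vorticity alone, slender rods
(alpha -> 1) are additionally aligned by strain.

Runs are interrupted by instantaneous stochastic reorientations: with
per-step probability dt/tau each swimmer rotates by +-theta_m0 (equal
probability) plus small Gaussian noise, which realizes exponential run lengths
of mean tau (a Poisson process).  theta_m0 = 70 deg models run-and-tumble
(E. coli-like), 180 deg models the run-reverse pattern of marine bacteria;
"simple" swimmers never turn.  The run time tau equals tau_0 in a homogeneous
environment and is modulated by chemotaxis otherwise.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "MotilityPattern",
    "SwimmerPopulation",
    "orientation_rate",
    "step_run",
    "draw_turn",
    "maybe_reorient",
]


@dataclass(frozen=True)
class MotilityPattern:
    """Turn-angle law and run-time statistics of one motility pattern.

    ``theta_m0`` is the nominal turn angle in degrees (None disables turning:
    a "simple" swimmer with tau -> infinity); ``sigma`` the Gaussian noise std
    in degrees; ``tau_0`` the mean run time in a homogeneous environment, in
    flow-time units.
    """

    theta_m0: Optional[float] = None
    sigma: float = 5.0
    tau_0: float = 1.0
    chemotactic: bool = False

    def __post_init__(self) -> None:
        if self.theta_m0 is not None and not (0.0 < self.theta_m0 <= 180.0):
            raise ValueError("theta_m0 must lie in (0, 180] degrees")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if not self.tau_0 > 0:
            raise ValueError("tau_0 must be positive")

    @property
    def enabled(self) -> bool:
        return self.theta_m0 is not None

    @classmethod
    def simple(cls, tau_0: float = 1.0) -> "MotilityPattern":
        return cls(theta_m0=None, tau_0=tau_0, chemotactic=False)

    @classmethod
    def run_and_tumble(cls, tau_0: float = 1.0, sigma: float = 5.0,
                       chemotactic: bool = False) -> "MotilityPattern":
        return cls(theta_m0=70.0, sigma=sigma, tau_0=tau_0, chemotactic=chemotactic)

    @classmethod
    def run_reverse(cls, tau_0: float = 1.0, sigma: float = 5.0,
                    chemotactic: bool = False) -> "MotilityPattern":
        return cls(theta_m0=180.0, sigma=sigma, tau_0=tau_0, chemotactic=chemotactic)


@dataclass
class SwimmerPopulation:
    """State of N swimmers sharing speed ``us`` and shape ``alpha``.

    Orientations are stored as angles theta (p = (cos theta, sin theta)), so
    unit norm is preserved exactly under integration.  ``tau`` holds each
    swimmer's current run time (tau_0 everywhere when chemotaxis is off);
    ``C_prev`` and ``Rb_rate`` carry the chemotaxis state between steps.
    """

    positions: np.ndarray  # (N, 2)
    theta: np.ndarray  # (N,)
    us: float
    alpha: float
    tau: np.ndarray  # (N,)
    C_prev: np.ndarray  # (N,)
    Rb_rate: np.ndarray  # (N,)

    def __post_init__(self) -> None:
        if not (0.0 <= self.alpha < 1.0):
            raise ValueError("alpha must lie in [0, 1)")
        if self.us < 0:
            raise ValueError("us must be >= 0")

    @property
    def n(self) -> int:
        return len(self.theta)

    @property
    def orientations(self) -> np.ndarray:
        """Unit orientation vectors p, shape (N, 2)."""
        return np.stack([np.cos(self.theta), np.sin(self.theta)], axis=1)

    @classmethod
    def random(cls, n: int, us: float, alpha: float, L: float,
               rng: np.random.Generator, tau_0: float = 1.0) -> "SwimmerPopulation":
        """Uniform random positions in [0, L)^2 and isotropic orientations."""
        return cls(
            positions=rng.uniform(0.0, L, size=(n, 2)),
            theta=rng.uniform(0.0, 2.0 * math.pi, size=n),
            us=us,
            alpha=alpha,
            tau=np.full(n, tau_0),
            C_prev=np.zeros(n),
            Rb_rate=np.zeros(n),
        )

    def copy(self) -> "SwimmerPopulation":
        return SwimmerPopulation(
            positions=self.positions.copy(),
            theta=self.theta.copy(),
            us=self.us,
            alpha=self.alpha,
            tau=self.tau.copy(),
            C_prev=self.C_prev.copy(),
            Rb_rate=self.Rb_rate.copy(),
        )


def orientation_rate(p: np.ndarray, omega: float, E: np.ndarray,
                     alpha: float) -> np.ndarray:
    """Jeffery rate dp/dt = (omega/2) p_perp + alpha (I - pp) E p.

    ``p`` must be a unit vector; the result is orthogonal to ``p`` (to within
    round-off) because both the rotation and the tangentially projected strain
    term are.  The 2D cross product ``omega x p`` is ``omega * (-p_y, p_x)``.
    """
    p = np.asarray(p, dtype=float)
    if abs(float(p @ p) - 1.0) > 1e-8:
        raise ValueError("p must be a unit vector (renormalize before calling)")
    E = np.asarray(E, dtype=float)
    perp = np.array([-p[1], p[0]])
    ep = E @ p
    return 0.5 * omega * perp + alpha * (ep - float(p @ ep) * p)


def _theta_rate(theta, omega, exx, exy, alpha):
    """Angle form of the Jeffery rate: dtheta/dt = omega/2 + alpha*(E_xy cos 2th - E_xx sin 2th)."""
    return 0.5 * omega + alpha * (exy * np.cos(2.0 * theta) - exx * np.sin(2.0 * theta))


def step_run(pop: SwimmerPopulation, flow, dt: float) -> SwimmerPopulation:
    """One 4th-order (RK4) step of translation and orientation for all swimmers.

    The flow is held at its current amplitudes over the step (its temporal
    process is advanced on the same clock by the caller), so the four stages
    sample a steady field.  Positions are wrapped into [0, L)^2 for periodic
    flows; analytic flows are globally defined and left unwrapped.
    """
    if not dt > 0:
        raise ValueError("dt must be positive")
    us, alpha = pop.us, pop.alpha
    x0, th0 = pop.positions, pop.theta

    def deriv(x, th):
        u, omega, exx, exy = flow.sample_fields(x)
        c, s = np.cos(th), np.sin(th)
        dx = u.copy()
        dx[:, 0] += us * c
        dx[:, 1] += us * s
        # cos/sin(2 theta) from the single-angle values (saves two transcendentals)
        dth = 0.5 * omega + alpha * (exy * (c * c - s * s) - exx * (2.0 * c * s))
        return dx, dth

    k1x, k1t = deriv(x0, th0)
    k2x, k2t = deriv(x0 + 0.5 * dt * k1x, th0 + 0.5 * dt * k1t)
    k3x, k3t = deriv(x0 + 0.5 * dt * k2x, th0 + 0.5 * dt * k2t)
    k4x, k4t = deriv(x0 + dt * k3x, th0 + dt * k3t)
    x = x0 + (dt / 6.0) * (k1x + 2.0 * k2x + 2.0 * k3x + k4x)
    th = th0 + (dt / 6.0) * (k1t + 2.0 * k2t + 2.0 * k3t + k4t)
    if getattr(flow, "periodic", False):
        x %= flow.L
    out = pop.copy()
    out.positions = x
    out.theta = th
    return out


def draw_turn(pattern: MotilityPattern, rng: np.random.Generator,
              size: Optional[int] = None) -> np.ndarray | float:
    """Draw signed turn angles in degrees: +-theta_m0 with equal probability
    plus N(0, sigma) noise."""
    if not pattern.enabled:
        raise ValueError("motility pattern has turning disabled (simple swimmer)")
    n = 1 if size is None else size
    sign = rng.choice([-1.0, 1.0], size=n)
    angles = sign * pattern.theta_m0 + rng.normal(0.0, pattern.sigma, size=n)
    return float(angles[0]) if size is None else angles


def maybe_reorient(pop: SwimmerPopulation, pattern: MotilityPattern, dt: float,
                   rng: np.random.Generator) -> SwimmerPopulation:
    """Apply at most one instantaneous turn per swimmer with probability dt/tau.

    Realizes the Poisson switching process: over many steps the run lengths
    are exponential with mean tau.  For a disabled pattern (simple swimmers)
    the population is returned unchanged.  A warning is raised when dt is not
    small against the homogeneous run time tau_0.
    """
    if not pattern.enabled:
        return pop
    if np.any(pop.tau <= 0):
        raise ValueError("run times tau must be positive")
    if dt > 0.5 * pattern.tau_0:
        warnings.warn(
            f"dt={dt} is not small compared with tau_0={pattern.tau_0}; "
            "the per-step Bernoulli turn probability is biased",
            stacklevel=2,
        )
    p_turn = np.minimum(dt / pop.tau, 1.0)
    mask = rng.random(pop.n) < p_turn
    if not mask.any():
        return pop
    turns = draw_turn(pattern, rng, size=int(mask.sum()))
    out = pop.copy()
    out.theta = out.theta.copy()
    out.theta[mask] += np.deg2rad(turns)
    return out
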