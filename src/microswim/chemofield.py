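"""Advected point food sources and the chemoattractant concentration field.

The n food sources (default 5) are light, small particles (Stokes number
St << 1) and therefore move as Lagrangian tracers, dx_s/dt = u(x_s, t).  Each
source continuously releases chemoattractant: the concentration C is advected
by the flow and decays at rate kappa everywhere except at the sources, where
it is held at the fixed value C0,

    dC/dt + u . grad C = -kappa C        (C = C0 at each source).

There is no molecular diffusion term in the model; the transport is solved
with a semi-Lagrangian scheme (RK2 back-trace, periodic bilinear
interpolation) on an M x M grid, followed by exact multiplicative decay
exp(-kappa dt) and a hard clamp of the grid cell containing each source to
C0.  The scheme is unconditionally stable and monotone (bilinear weights are
convex), so 0 <= C <= C0 holds at all times.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "SourceSet",
    "ChemoField",
    "advect_sources",
    "step_field",
    "sample_concentration",
    "spin_up",
]


@dataclass
class SourceSet:
    """Point food sources advected as tracers; each clamps C to C0 locally."""

    positions: np.ndarray  # (n, 2)
    C0: float = 1.0

    def __post_init__(self) -> None:
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        if len(self.positions) < 1:
            raise ValueError("at least one source is required")

    @property
    def n(self) -> int:
        return len(self.positions)

    @classmethod
    def random(cls, n: int, L: float, rng: np.random.Generator,
               C0: float = 1.0) -> "SourceSet":
        """n sources placed uniformly at random in the periodic box."""
        return cls(positions=rng.uniform(0.0, L, size=(n, 2)), C0=C0)

    def copy(self) -> "SourceSet":
        return SourceSet(positions=self.positions.copy(), C0=self.C0)


@dataclass
class ChemoField:
    """Gridded chemoattractant concentration on [0, L)^2.

    ``C[i, j]`` is the value at node (i*L/M, j*L/M).  ``kappa`` is the decay
    rate (1/flow time); ``sources`` the clamped point sources.
    """

    C: np.ndarray  # (M, M)
    L: float
    kappa: float
    sources: SourceSet

    def __post_init__(self) -> None:
        self.C = np.asarray(self.C, dtype=float)
        if self.C.ndim != 2 or self.C.shape[0] != self.C.shape[1]:
            raise ValueError("C must be a square M x M grid")
        if self.kappa < 0:
            raise ValueError("kappa must be >= 0")

    @property
    def M(self) -> int:
        return self.C.shape[0]

    @classmethod
    def zeros(cls, M: int, L: float, kappa: float, sources: SourceSet) -> "ChemoField":
        return cls(C=np.zeros((M, M)), L=L, kappa=kappa, sources=sources)

    def copy(self) -> "ChemoField":
        return ChemoField(C=self.C.copy(), L=self.L, kappa=self.kappa,
                          sources=self.sources.copy())

    def clamp_sources(self) -> None:
        """Reset the grid cell containing each source to C0."""
        M = self.M
        idx = np.floor(self.sources.positions * (M / self.L) + 0.5).astype(int) % M
        self.C[idx[:, 0], idx[:, 1]] = self.sources.C0


def _bilinear_periodic(grid: np.ndarray, pos: np.ndarray, L: float) -> np.ndarray:
    """Periodic bilinear interpolation of one (M, M) grid at (N, 2) points."""
    from .flow import _bilinear_stack_jit

    if _bilinear_stack_jit is not None:
        return _bilinear_stack_jit(grid[None, :, :],
                                   np.ascontiguousarray(pos[:, 0]),
                                   np.ascontiguousarray(pos[:, 1]), L)[0]
    M = grid.shape[0]
    s = (pos % L) * (M / L)
    i0 = np.floor(s).astype(np.int64)
    f = s - i0
    i0 %= M
    i1 = (i0 + 1) % M
    fx, fy = f[:, 0], f[:, 1]
    return (
        grid[i0[:, 0], i0[:, 1]] * (1 - fx) * (1 - fy)
        + grid[i1[:, 0], i0[:, 1]] * fx * (1 - fy)
        + grid[i0[:, 0], i1[:, 1]] * (1 - fx) * fy
        + grid[i1[:, 0], i1[:, 1]] * fx * fy
    )


def advect_sources(sources: SourceSet, flow, dt: float) -> SourceSet:
    """Advance the tracer sources with the local fluid velocity (RK4).

    Same integrator order and clock as the swimmers; positions wrapped into
    the periodic domain for periodic flows.
    """
    if not dt > 0:
        raise ValueError("dt must be positive")
    x0 = sources.positions

    def vel(x):
        return flow.sample_fields(x)[0]

    k1 = vel(x0)
    k2 = vel(x0 + 0.5 * dt * k1)
    k3 = vel(x0 + 0.5 * dt * k2)
    k4 = vel(x0 + dt * k3)
    x = x0 + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
    if getattr(flow, "periodic", False):
        x %= flow.L
    return SourceSet(positions=x, C0=sources.C0)


def step_field(field: ChemoField, flow, dt: float) -> ChemoField:
    """One semi-Lagrangian advection + decay + source-clamp step (in place).

    Back-trace: departure points found with an RK2 midpoint rule using the
    velocity sampled at grid nodes; the concentration is interpolated there
    bilinearly, multiplied by exp(-kappa dt) (exact decay), and the cells
    containing sources are reset to C0.  Callers advect the sources first.
    """
    if not dt > 0:
        raise ValueError("dt must be positive")
    M, L = field.M, field.L
    nodes = (np.arange(M) * (L / M))
    gx, gy = np.meshgrid(nodes, nodes, indexing="ij")
    pos = np.column_stack([gx.ravel(), gy.ravel()])
    u0 = flow.sample_fields(pos)[0]
    mid = pos - 0.5 * dt * u0
    umid = flow.sample_fields(mid)[0]
    dep = pos - dt * umid
    c = _bilinear_periodic(field.C, dep, L).reshape(M, M)
    field.C = c * math.exp(-field.kappa * dt)
    field.clamp_sources()
    return field


def sample_concentration(field: ChemoField, positions) -> np.ndarray:
    """Bilinear interpolation of the concentration at (wrapped) positions."""
    pos = np.atleast_2d(np.asarray(positions, dtype=float))
    if pos.size == 0:
        return np.zeros(0)
    return _bilinear_periodic(field.C, pos, field.L)


def spin_up(field: ChemoField, sources: SourceSet, flow, t_spin: float,
            dt: float = 0.01, sampler=None):
    """Co-evolve flow, sources and concentration for t_spin before swimmers enter.

    ``sampler`` may be a :class:`~microswim.flow.GriddedFlow` wrapping ``flow``
    to reuse one spectral synthesis per step for both the tracer advection and
    the field transport.  Returns the evolved ``(field, sources, flow)``.
    """
    from .flow import FlowState, advance_flow  # local import to avoid a cycle

    if t_spin < 0:
        raise ValueError("t_spin must be >= 0")
    nsteps = int(round(t_spin / dt))
    vel = sampler if sampler is not None else flow
    for _ in range(nsteps):
        if isinstance(flow, FlowState):
            advance_flow(flow, dt)
        sources = advect_sources(sources, vel, dt)
        field.sources = sources
        step_field(field, vel, dt)
    return field, sources, flow
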