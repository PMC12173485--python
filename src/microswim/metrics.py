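"""Observables: flow-alignment statistics and nearest-food-source distances.

Alignment between the swimming direction p and the local flow velocity u is
measured by the unsigned angle theta_u in [0, 180] degrees and summarized by

    <theta_u>     = (1/Np) sum_i |theta_u,i|          (90 deg if symmetric)
    <|cos theta_u|> = (1/Np) sum_i |cos theta_u,i|    (1 for perfect alignment)

the second deliberately not distinguishing head from tail.  Tracking skill is
the population-mean distance to the closest food source <d> (periodic
minimum-image metric), normalized by the baseline d* of uniformly random
non-swimming particles against the same source trajectory, so <d>/d* = 1
means no tracking and smaller is better.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .chemofield import SourceSet

__all__ = [
    "AlignmentStats",
    "TrackingStats",
    "alignment_stats",
    "nearest_source_distance",
    "random_baseline",
    "advected_length_scale",
]


@dataclass
class AlignmentStats:
    """Per-snapshot alignment-angle statistics (degrees)."""

    theta_u: np.ndarray  # per-swimmer unsigned angle, [0, 180]
    mean_theta_u: float
    mean_abs_cos: float
    histogram: np.ndarray  # fractions N/Np per bin, sums to 1
    bin_edges: np.ndarray  # degrees
    n_excluded: int  # swimmers at points with |u| ~ 0

    @property
    def asymmetry(self) -> float:
        """Fraction of swimmers with theta_u < 90 deg minus fraction above.

        Positive values mean predominant head-alignment with the flow;
        zero for a distribution symmetric about 90 deg.
        """
        return float(np.mean(self.theta_u < 90.0) - np.mean(self.theta_u > 90.0))


@dataclass
class TrackingStats:
    """Population-mean nearest-source distance and its random baseline."""

    d_mean: float
    d_star: float

    @property
    def d_norm(self) -> float:
        return self.d_mean / self.d_star


def alignment_stats(pop, flow, bins: int = 18) -> AlignmentStats:
    """Angle statistics between swimmer orientations and the local velocity.

    Swimmers sitting at points where |u| < 1e-12 carry no defined angle; they
    are excluded from the statistics and counted in ``n_excluded``.
    """
    if pop.n == 0:
        raise ValueError("empty population")
    u = flow.sample_fields(pop.positions)[0]
    speed = np.hypot(u[:, 0], u[:, 1])
    ok = speed > 1e-12
    n_excluded = int((~ok).sum())
    if not ok.any():
        raise ValueError("flow velocity vanishes at every swimmer position")
    p = pop.orientations[ok]
    cos = np.einsum("ij,ij->i", p, u[ok]) / speed[ok]
    theta = np.degrees(np.arccos(np.clip(cos, -1.0, 1.0)))
    edges = np.linspace(0.0, 180.0, bins + 1)
    hist, _ = np.histogram(theta, bins=edges)
    return AlignmentStats(
        theta_u=theta,
        mean_theta_u=float(theta.mean()),
        mean_abs_cos=float(np.abs(cos).mean()),
        histogram=hist / hist.sum(),
        bin_edges=edges,
        n_excluded=n_excluded,
    )


def _min_image_dist(points: np.ndarray, sources: np.ndarray, L: float) -> np.ndarray:
    """Per-point minimum-image distance to the closest source."""
    d = points[:, None, :] - sources[None, :, :]
    d -= L * np.round(d / L)
    return np.sqrt((d * d).sum(axis=2)).min(axis=1)


def nearest_source_distance(positions, sources: SourceSet, L: float):
    """Mean and per-swimmer periodic distance to the closest food source."""
    if sources.n < 1:
        raise ValueError("at least one source required")
    pts = np.atleast_2d(np.asarray(positions, dtype=float))
    dist = _min_image_dist(pts, sources.positions, L)
    return float(dist.mean()), dist


def random_baseline(sources: SourceSet, L: float, n_samples: int,
                    rng: np.random.Generator) -> float:
    """Monte-Carlo d*: mean nearest-source distance of uniform random points.

    One snapshot's baseline; the driver averages it over the same source
    trajectory as the experiment.
    """
    if n_samples < 1000:
        raise ValueError("n_samples must be >= 1000 for a stable baseline")
    pts = rng.uniform(0.0, L, size=(n_samples, 2))
    return float(_min_image_dist(pts, sources.positions, L).mean())


def advected_length_scale(tau_0: float, uf: float, lambda_f: float) -> float:
    """l_f / lambda_f = tau_0 * uf / lambda_f: distance (in vortex sizes) the
    flow advects a swimmer during one mean run."""
    if tau_0 <= 0 or uf <= 0 or lambda_f <= 0:
        raise ValueError("tau_0, uf and lambda_f must be positive")
    return tau_0 * uf / lambda_f
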