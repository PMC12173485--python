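"""Experiment orchestration: configuration, seeding, and the two experiment
families — flow-alignment scans (no food) and chemotactic tracking runs.

Seeding policy: one master seed per simulation is split into independent
named streams (flow, sources, swimmers, baseline) via ``SeedSequence``.  The
flow and source realizations therefore depend only on the master seed, not on
the motility pattern, so runs that differ only in pattern are paired on
identical flows — the comparisons between run-reverse and run-and-tumble are
not confounded by flow realization.

Default experiment sizes mirror the standard setups: 10^4–5x10^4 swimmers for
alignment scans, 500 for tracking; tau_0 = tf, kappa = 0.01, five food
sources, spin-up of 32 tau_f before chemotactic swimmers are released.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .chemofield import ChemoField, SourceSet, advect_sources, step_field
from .chemotaxis import ChemotaxisParams, update_run_times
from .flow import AnalyticFlow, FlowParams, FlowState, GriddedFlow, advance_flow, init_flow
from .metrics import (AlignmentStats, TrackingStats, alignment_stats,
                      nearest_source_distance, random_baseline)
from .swimmers import MotilityPattern, SwimmerPopulation, maybe_reorient, step_run

__all__ = [
    "SwimmerConfig",
    "ChemoConfig",
    "RunConfig",
    "SimConfig",
    "AlignmentResult",
    "TrackingResult",
    "TrackingEnvironment",
    "run_alignment_experiment",
    "prepare_tracking_environment",
    "run_tracking_experiment",
    "run_hill_experiment",
    "make_fixture",
    "serialize_fixture",
]

logger = logging.getLogger("microswim")

_PATTERNS = {"simple", "run_reverse", "run_and_tumble"}


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SwimmerConfig:
    n: int = 10_000
    us: float = 0.5
    alpha: float = 0.98
    pattern: str = "simple"
    tau_0: float = 1.0
    sigma: float = 5.0

    def __post_init__(self) -> None:
        if self.pattern not in _PATTERNS:
            raise ValueError(
                f"swimmers.pattern: {self.pattern!r} not in {sorted(_PATTERNS)}")
        if self.n < 1:
            raise ValueError("swimmers.n must be >= 1")

    def make_pattern(self, chemotactic: bool = False) -> MotilityPattern:
        if self.pattern == "simple":
            return MotilityPattern.simple(tau_0=self.tau_0)
        factory = (MotilityPattern.run_reverse if self.pattern == "run_reverse"
                   else MotilityPattern.run_and_tumble)
        return factory(tau_0=self.tau_0, sigma=self.sigma, chemotactic=chemotactic)


@dataclass(frozen=True)
class ChemoConfig:
    enabled: bool = False
    kappa: float = 0.01
    M: int = 256
    n_sources: int = 5
    C0: float = 1.0
    spin_up_time: Optional[float] = None  # None -> 32 * tau_f

    def __post_init__(self) -> None:
        if self.kappa < 0:
            raise ValueError("chemo.kappa must be >= 0")
        if self.n_sources < 1:
            raise ValueError("chemo.n_sources must be >= 1")


@dataclass(frozen=True)
class RunConfig:
    dt: float = 0.01
    t_end: float = 60.0
    snapshot_every: float = 0.1
    transient: float = 2.0
    seed: int = 0
    flow_grid_n: int = 256
    baseline_samples: int = 2000
    average_from: float = 10.0
    output_dir: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.dt > 0:
            raise ValueError("run.dt must be positive")
        if not self.t_end > self.dt:
            raise ValueError("run.t_end must exceed run.dt")
        ratio = self.snapshot_every / self.dt
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValueError("run.snapshot_every must be a multiple of run.dt")


@dataclass
class SimConfig:
    flow: FlowParams = field(default_factory=FlowParams)
    swimmers: SwimmerConfig = field(default_factory=SwimmerConfig)
    chemo: ChemoConfig = field(default_factory=ChemoConfig)
    chemotaxis: ChemotaxisParams = field(default_factory=ChemotaxisParams)
    run: RunConfig = field(default_factory=RunConfig)

    def to_dict(self) -> dict:
        return {
            "flow": dataclasses.asdict(self.flow),
            "swimmers": dataclasses.asdict(self.swimmers),
            "chemo": dataclasses.asdict(self.chemo),
            "chemotaxis": dataclasses.asdict(self.chemotaxis),
            "run": dataclasses.asdict(self.run),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        return cls(
            flow=FlowParams(**d.get("flow", {})),
            swimmers=SwimmerConfig(**d.get("swimmers", {})),
            chemo=ChemoConfig(**d.get("chemo", {})),
            chemotaxis=ChemotaxisParams(**d.get("chemotaxis", {})),
            run=RunConfig(**d.get("run", {})),
        )

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "SimConfig":
        return cls.from_dict(yaml.safe_load(text) or {})

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:12]

    @property
    def spin_up_time(self) -> float:
        if self.chemo.spin_up_time is not None:
            return self.chemo.spin_up_time
        return 32.0 * self.flow.tau_f


def _streams(seed: int):
    """Named independent RNG streams derived from the master seed."""
    children = np.random.SeedSequence(seed).spawn(4)
    flow_seed = int(children[0].generate_state(1)[0] % (2**31))
    return {
        "flow_seed": flow_seed,
        "sources": np.random.default_rng(children[1]),
        "swimmers": np.random.default_rng(children[2]),
        "baseline": np.random.default_rng(children[3]),
    }


# ---------------------------------------------------------------------------
# alignment experiments (no food, Figs 3/4-style)
# ---------------------------------------------------------------------------


@dataclass
class AlignmentResult:
    series: pd.DataFrame  # t, mean_theta_u, mean_abs_cos, asymmetry
    final: AlignmentStats
    config: SimConfig

    @property
    def time_mean_theta_u(self) -> float:
        return float(self.series["mean_theta_u"].mean())

    @property
    def time_mean_abs_cos(self) -> float:
        return float(self.series["mean_abs_cos"].mean())


def run_alignment_experiment(config: SimConfig) -> AlignmentResult:
    """Evolve the flow plus a non-chemotactic population and record alignment.

    Snapshot statistics are taken every ``snapshot_every`` after the
    ``transient``; the final :class:`AlignmentStats` (with the full theta_u
    histogram) is evaluated at t_end.  Deterministic given the master seed.
    """
    if config.chemo.enabled:
        raise ValueError("run.alignment requires chemo.enabled = False")
    streams = _streams(config.run.seed)
    flow_params = dataclasses.replace(config.flow, seed=streams["flow_seed"])
    state = init_flow(flow_params)
    sampler = GriddedFlow(state, config.run.flow_grid_n)
    sw = config.swimmers
    pop = SwimmerPopulation.random(sw.n, sw.us, sw.alpha, flow_params.L,
                                   streams["swimmers"], tau_0=sw.tau_0)
    pattern = sw.make_pattern(chemotactic=False)
    rc = config.run
    nsteps = int(round(rc.t_end / rc.dt))
    every = int(round(rc.snapshot_every / rc.dt))
    records = []
    tick = max(1, nsteps // 10)
    for step in range(1, nsteps + 1):
        advance_flow(state, rc.dt)
        pop = step_run(pop, sampler, rc.dt)
        pop = maybe_reorient(pop, pattern, rc.dt, streams["swimmers"])
        t = step * rc.dt
        if step % every == 0 and t > rc.transient:
            st = alignment_stats(pop, sampler)
            records.append((t, st.mean_theta_u, st.mean_abs_cos, st.asymmetry))
        if step % tick == 0:
            logger.info("alignment %s: %3.0f%% (t=%.1f)", sw.pattern,
                        100.0 * step / nsteps, t)
    final = alignment_stats(pop, sampler)
    series = pd.DataFrame(records,
                          columns=["t", "mean_theta_u", "mean_abs_cos", "asymmetry"])
    return AlignmentResult(series=series, final=final, config=config)


# ---------------------------------------------------------------------------
# tracking experiments (Figs 5/6-style)
# ---------------------------------------------------------------------------


@dataclass
class TrackingEnvironment:
    """Spun-up flow + advected sources + chemoattractant field, reusable (via
    copies) across motility patterns for paired comparisons."""

    state: FlowState
    sources: SourceSet
    field: ChemoField
    grid_n: int

    def copy(self) -> "TrackingEnvironment":
        return TrackingEnvironment(
            state=self.state.copy(),
            sources=self.sources.copy(),
            field=self.field.copy(),
            grid_n=self.grid_n,
        )


def prepare_tracking_environment(config: SimConfig) -> TrackingEnvironment:
    """Spin up flow, tracer sources and concentration field for 32 tau_f
    (by default) so the plume structure reaches a statistical steady state
    before swimmers are added."""
    streams = _streams(config.run.seed)
    flow_params = dataclasses.replace(config.flow, seed=streams["flow_seed"])
    state = init_flow(flow_params)
    sampler = GriddedFlow(state, config.run.flow_grid_n)
    sources = SourceSet.random(config.chemo.n_sources, flow_params.L,
                               streams["sources"], C0=config.chemo.C0)
    fld = ChemoField.zeros(config.chemo.M, flow_params.L, config.chemo.kappa, sources)
    fld.clamp_sources()
    dt = config.run.dt
    nsteps = int(round(config.spin_up_time / dt))
    tick = max(1, nsteps // 10)
    for step in range(1, nsteps + 1):
        advance_flow(state, dt)
        sources = advect_sources(sources, sampler, dt)
        fld.sources = sources
        step_field(fld, sampler, dt)
        if step % tick == 0:
            logger.info("spin-up: %3.0f%% (t=%.1f)", 100.0 * step / nsteps, step * dt)
    return TrackingEnvironment(state=state, sources=sources, field=fld,
                               grid_n=config.run.flow_grid_n)


@dataclass
class TrackingResult:
    series: pd.DataFrame  # t, d_mean, d_star, d_norm
    config: SimConfig

    @property
    def time_avg(self) -> TrackingStats:
        """Time-averaged statistics over the configured averaging window."""
        win = self.series[self.series["t"] >= self.config.run.average_from]
        if len(win) == 0:
            win = self.series
        return TrackingStats(d_mean=float(win["d_mean"].mean()),
                             d_star=float(win["d_star"].mean()))


def run_tracking_experiment(config: SimConfig,
                            env: Optional[TrackingEnvironment] = None
                            ) -> TrackingResult:
    """Release chemotactic swimmers into a spun-up environment and follow the
    population-mean nearest-source distance.

    ``env`` (from :func:`prepare_tracking_environment`) is copied, never
    mutated, so several patterns can be run against the identical flow and
    source realization.  Time in the returned series is measured from the
    moment the swimmers are added.  d* is recomputed by Monte-Carlo at every
    snapshot against the current source positions.
    """
    if not config.chemo.enabled:
        raise ValueError("run_tracking_experiment requires chemo.enabled = True")
    if env is None:
        env = prepare_tracking_environment(config)
    env = env.copy()
    state, sources, fld = env.state, env.sources, env.field
    sampler = GriddedFlow(state, env.grid_n)
    streams = _streams(config.run.seed)
    sw = config.swimmers
    pop = SwimmerPopulation.random(sw.n, sw.us, sw.alpha, state.params.L,
                                   streams["swimmers"], tau_0=sw.tau_0)
    pattern = sw.make_pattern(chemotactic=True)
    from .chemofield import sample_concentration

    pop.C_prev = sample_concentration(fld, pop.positions)
    rc = config.run
    nsteps = int(round(rc.t_end / rc.dt))
    every = int(round(rc.snapshot_every / rc.dt))
    records = []
    tick = max(1, nsteps // 10)
    for step in range(1, nsteps + 1):
        advance_flow(state, rc.dt)
        sources = advect_sources(sources, sampler, rc.dt)
        fld.sources = sources
        step_field(fld, sampler, rc.dt)
        pop = step_run(pop, sampler, rc.dt)
        update_run_times(pop, fld, rc.dt, config.chemotaxis, flow=sampler)
        if pattern.enabled:
            pop = maybe_reorient(pop, pattern, rc.dt, streams["swimmers"])
        if step % every == 0:
            d_mean, _ = nearest_source_distance(pop.positions, sources,
                                                state.params.L)
            d_star = random_baseline(sources, state.params.L,
                                     rc.baseline_samples, streams["baseline"])
            records.append((step * rc.dt, d_mean, d_star, d_mean / d_star))
        if step % tick == 0:
            logger.info("tracking %s a=%.2f: %3.0f%% (t=%.1f, d/d*=%.2f)",
                        sw.pattern, sw.alpha, 100.0 * step / nsteps,
                        step * rc.dt, records[-1][3] if records else math.nan)
    series = pd.DataFrame(records, columns=["t", "d_mean", "d_star", "d_norm"])
    return TrackingResult(series=series, config=config)


# ---------------------------------------------------------------------------
# static-hill functional experiment (no flow)
# ---------------------------------------------------------------------------


def run_hill_experiment(n: int, pattern: MotilityPattern,
                        chemo: ChemotaxisParams, t_end: float,
                        dt: float = 0.01, seed: int = 0, us: float = 1.0,
                        L: float = 2 * math.pi, sigma: float = 1.0,
                        M: int = 128, C0: float = 1.0,
                        snapshot_every: float = 0.5) -> pd.DataFrame:
    """Chemotactic swimmers in a frozen radial concentration hill, no flow.

    The field is a Gaussian hill of width ``sigma`` centred in the box and
    never updated, isolating the receptor-kinetics/run-time feedback from all
    hydrodynamics.  Returns a time series of the population-mean (periodic)
    distance to the peak.
    """
    fix = make_fixture("gradient-hill", {"M": M, "L": L, "sigma": sigma, "C0": C0})
    centre = np.array([L / 2.0, L / 2.0])
    fld = ChemoField(C=np.asarray(fix["grid"]), L=L, kappa=0.0,
                     sources=SourceSet(positions=centre[None, :], C0=C0))
    flow = _PeriodicQuiescent(L)
    rng = np.random.default_rng(seed)
    pop = SwimmerPopulation.random(n, us, 0.0, L, rng, tau_0=pattern.tau_0)
    from .chemofield import sample_concentration

    pop.C_prev = sample_concentration(fld, pop.positions)
    nsteps = int(round(t_end / dt))
    every = int(round(snapshot_every / dt))
    records = []
    for step in range(1, nsteps + 1):
        pop = step_run(pop, flow, dt)
        update_run_times(pop, fld, dt, chemo)
        if pattern.enabled:
            pop = maybe_reorient(pop, pattern, dt, rng)
        if step % every == 0:
            d = pop.positions - centre
            d -= L * np.round(d / L)
            records.append((step * dt, float(np.hypot(d[:, 0], d[:, 1]).mean())))
    return pd.DataFrame(records, columns=["t", "mean_dist"])


class _PeriodicQuiescent:
    """Still fluid on a periodic box (keeps swimmers inside the hill domain)."""

    periodic = True

    def __init__(self, L: float):
        self.L = L

    def sample_fields(self, positions):
        pos = np.atleast_2d(np.asarray(positions, dtype=float))
        npts = pos.shape[0]
        z = np.zeros(npts)
        return np.zeros((npts, 2)), z, z, z


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------


def make_fixture(kind: str, params: Optional[dict] = None) -> dict:
    """Deterministic test inputs: analytic flow descriptors, a frozen plume,
    or a radial concentration hill.  Serialize with :func:`serialize_fixture`
    for byte-stable output."""
    params = dict(params or {})
    if kind == "analytic-flow":
        flow_kind = params.pop("kind", "simple_shear")
        AnalyticFlow(flow_kind, **params)  # validates
        return {"fixture": "analytic-flow", "kind": flow_kind, "params": params}
    if kind == "gradient-hill":
        M = int(params.get("M", 64))
        L = float(params.get("L", 2 * math.pi))
        sigma = float(params.get("sigma", 1.0))
        C0 = float(params.get("C0", 1.0))
        nodes = np.arange(M) * (L / M)
        gx, gy = np.meshgrid(nodes, nodes, indexing="ij")
        dx = gx - L / 2.0
        dy = gy - L / 2.0
        dx -= L * np.round(dx / L)
        dy -= L * np.round(dy / L)
        grid = C0 * np.exp(-(dx * dx + dy * dy) / (2.0 * sigma * sigma))
        return {"fixture": "gradient-hill", "M": M, "L": L, "sigma": sigma,
                "C0": C0, "grid": grid.tolist()}
    if kind == "frozen-plume":
        M = int(params.get("M", 64))
        L = float(params.get("L", 2 * math.pi))
        gamma = float(params.get("gamma", 0.3))
        kappa = float(params.get("kappa", 0.5))
        t_end = float(params.get("t", 10.0))
        dt = float(params.get("dt", 0.01))
        src = SourceSet(positions=np.array([[L / 2.0, 0.75 * L]]), C0=1.0)
        fld = ChemoField.zeros(M, L, kappa, src)
        fld.clamp_sources()
        flow = AnalyticFlow.simple_shear(gamma)
        for _ in range(int(round(t_end / dt))):
            step_field(fld, flow, dt)
        return {"fixture": "frozen-plume", "M": M, "L": L, "gamma": gamma,
                "kappa": kappa, "t": t_end, "source": src.positions[0].tolist(),
                "grid": fld.C.tolist()}
    raise ValueError(f"unknown fixture kind: {kind!r}")


def serialize_fixture(fixture: dict) -> bytes:
    """Canonical JSON bytes (sorted keys); identical inputs give identical bytes."""
    return json.dumps(fixture, sort_keys=True).encode()
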