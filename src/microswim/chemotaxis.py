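"""Receptor-level chemotaxis: concentration sensing and run-time modulation.

A bacterium senses the rate of change of chemoattractant concentration along
its own trajectory, DC/Dt, which drives the fraction of bound (activated)
membrane receptors Rb through saturating receptor kinetics,

    dRb/dt = Kd / (Kd + C)^2 * DC/Dt,

where Kd is the receptor half-saturation constant.  The mean run time is then
modulated exponentially,

    tau = tau_0 * exp(alpha_c * dRb/dt),

so runs up-gradient are extended and runs down-gradient contracted; the
per-step turn probability dt/tau used by the motility model picks this up
directly.  Defaults follow the standard parametrization: alpha_c = 300 (time
units), Kd/C0 = 1, tau_0 = 1, with the simulation clock anchored so one flow
time unit corresponds to one second.

Two readings of DC/Dt are supported.  The default, ``swimming_only``,
evaluates DC/Dt = dC/dt + us p . grad C: the perceived signal combines the
field's local time change with the swimmer's own motion through it, but NOT
the passive sweeping by the fluid (being carried with the flow, together with
the plume, produces no perceived change).  This sensing makes hydrodynamic
alignment the deciding factor in source tracking.  The ``trajectory`` variant
instead takes the full finite difference of the sampled concentration along
the actual path (advection included), for sensitivity checks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .chemofield import ChemoField, sample_concentration

__all__ = [
    "ChemotaxisParams",
    "experienced_rate",
    "receptor_rate",
    "run_time",
    "update_run_times",
]

_EXP_CLAMP = 50.0  # |alpha_c * dRb/dt| beyond this saturates tau


@dataclass(frozen=True)
class ChemotaxisParams:
    """Chemotaxis parameters: amplification alpha_c (time units), receptor
    half-saturation Kd (units of C0) and base run time tau_0."""

    alpha_c: float = 300.0
    Kd: float = 1.0
    tau_0: float = 1.0
    variant: str = "swimming_only"

    def __post_init__(self) -> None:
        if self.alpha_c < 0:
            raise ValueError("alpha_c must be >= 0")
        if not self.Kd > 0:
            raise ValueError("Kd must be positive")
        if not self.tau_0 > 0:
            raise ValueError("tau_0 must be positive")
        if self.variant not in {"trajectory", "swimming_only"}:
            raise ValueError("variant must be 'trajectory' or 'swimming_only'")


def experienced_rate(C_now, C_prev, dt: float):
    """Discrete material rate (C_now - C_prev)/dt along the swimmer path."""
    if not dt > 0:
        raise ValueError("dt must be positive")
    return (np.asarray(C_now, dtype=float) - np.asarray(C_prev, dtype=float)) / dt


def receptor_rate(C, dCdt, Kd: float):
    """dRb/dt = Kd/(Kd + C)^2 * DC/Dt; saturates to zero for C >> Kd."""
    C = np.asarray(C, dtype=float)
    return Kd / (Kd + C) ** 2 * np.asarray(dCdt, dtype=float)


def run_time(Rb_rate, params: ChemotaxisParams):
    """tau = tau_0 * exp(alpha_c * dRb/dt), exponent clamped to +-50."""
    x = np.clip(params.alpha_c * np.asarray(Rb_rate, dtype=float),
                -_EXP_CLAMP, _EXP_CLAMP)
    return params.tau_0 * np.exp(x)


def update_run_times(pop, field: ChemoField, dt: float,
                     params: ChemotaxisParams, flow=None) -> None:
    """Refresh per-swimmer run times from the concentration along the path.

    Samples C at the current (post-step) positions, forms the discrete
    material rate against the previous sample, applies the receptor kinetics
    and the exponential run-time law, and stores C_prev/Rb_rate/tau in place
    on the population.  With ``variant='swimming_only'`` the fluid-advection
    contribution u . grad C (from the gridded field gradient) is subtracted,
    matching the alternative reading where only self-propulsion contributes.
    """
    C_now = sample_concentration(field, pop.positions)
    rate = experienced_rate(C_now, pop.C_prev, dt)
    if params.variant == "swimming_only" and flow is not None:
        u = flow.sample_fields(pop.positions)[0]
        h = field.L / field.M
        gx = (np.roll(field.C, -1, axis=0) - np.roll(field.C, 1, axis=0)) / (2 * h)
        gy = (np.roll(field.C, -1, axis=1) - np.roll(field.C, 1, axis=1)) / (2 * h)
        from .chemofield import _bilinear_periodic

        grad = np.column_stack([
            _bilinear_periodic(gx, pop.positions, field.L),
            _bilinear_periodic(gy, pop.positions, field.L),
        ])
        rate = rate - np.einsum("ij,ij->i", u, grad)
    pop.Rb_rate = receptor_rate(C_now, rate, params.Kd)
    pop.tau = run_time(pop.Rb_rate, params)
    pop.C_prev = C_now
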