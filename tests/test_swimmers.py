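"""Swimmer kinematics: Jeffery orientation dynamics, run integration, and the
stochastic reorientation (tumble/reverse) process."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate, stats

from microswim import (AnalyticFlow, FlowParams, GriddedFlow, MotilityPattern,
                       SwimmerPopulation, draw_turn, init_flow, maybe_reorient,
                       orientation_rate, step_run)
from microswim.swimmers import _theta_rate

from conftest import make_population

TWO_PI = 2 * math.pi


def single_swimmer(theta=0.0, pos=(0.0, 0.0), us=0.0, alpha=0.0):
    return SwimmerPopulation(
        positions=np.array([pos], dtype=float), theta=np.array([theta]),
        us=us, alpha=alpha, tau=np.ones(1), C_prev=np.zeros(1),
        Rb_rate=np.zeros(1))


class TestOrientationRate:
    def test_sphere_in_pure_strain_does_not_rotate(self):
        E = np.array([[0.3, 0.1], [0.1, -0.3]])
        dp = orientation_rate(np.array([1.0, 0.0]), 0.0, E, alpha=0.0)
        np.testing.assert_allclose(dp, 0.0)

    def test_sphere_rotates_at_half_vorticity(self):
        # solid-body rotation at Omega has omega = 2*Omega -> rate Omega
        p = np.array([1.0, 0.0])
        dp = orientation_rate(p, 2 * 0.7, np.zeros((2, 2)), alpha=0.0)
        np.testing.assert_allclose(dp, [0.0, 0.7], atol=1e-15)

    def test_non_unit_p_rejected(self):
        with pytest.raises(ValueError):
            orientation_rate(np.array([1.0, 1.0]), 0.0, np.zeros((2, 2)), 0.5)

    @settings(derandomize=True, max_examples=50)
    @given(theta=st.floats(0, TWO_PI), omega=st.floats(-5, 5),
           exx=st.floats(-2, 2), exy=st.floats(-2, 2),
           alpha=st.floats(0, 0.99))
    def test_rate_orthogonal_and_matches_angle_form(self, theta, omega, exx,
                                                    exy, alpha):
        """dp/dt is orthogonal to p and equals the scalar angle form."""
        p = np.array([math.cos(theta), math.sin(theta)])
        E = np.array([[exx, exy], [exy, -exx]])
        dp = orientation_rate(p, omega, E, alpha)
        assert abs(dp @ p) < 1e-12
        dth = _theta_rate(theta, omega, exx, exy, alpha)
        perp = np.array([-p[1], p[0]])
        assert abs(dth - dp @ perp) < 1e-12


class TestRunIntegration:
    @pytest.mark.parametrize("r", [2.0, 5.0])
    def test_jeffery_period_in_simple_shear(self, r):
        """Tumbling period of an ellipsoid in shear: T = 2*pi*(r + 1/r)/gamma."""
        gamma = 1.0
        alpha = (r * r - 1) / (r * r + 1)
        flow = AnalyticFlow.simple_shear(gamma)
        pop = single_swimmer(theta=0.3, alpha=alpha)
        th0 = pop.theta[0]
        dt, t = 0.01, 0.0
        prev = th0
        while pop.theta[0] > th0 - TWO_PI:
            prev = pop.theta[0]
            pop = step_run(pop, flow, dt)
            t += dt
        frac = (prev - (th0 - TWO_PI)) / (prev - pop.theta[0])
        period = t - dt + frac * dt
        expected = TWO_PI * (r + 1 / r) / gamma
        assert abs(period - expected) / expected < 1e-3

    def test_stationary_without_swimming_in_still_fluid(self):
        pop = single_swimmer(pos=(1.0, 2.0), us=0.0)
        out = step_run(pop, AnalyticFlow.quiescent(), 0.5)
        np.testing.assert_array_equal(out.positions, pop.positions)

    def test_pure_swimming_displacement(self):
        pop = single_swimmer(theta=0.0, us=1.0)
        out = step_run(pop, AnalyticFlow.quiescent(), 0.1)
        np.testing.assert_allclose(out.positions[0], [0.1, 0.0], atol=1e-14)

    def test_passive_sphere_follows_tracer_trajectory(self):
        """us=0, alpha=0 swimmer in a cellular flow matches a high-accuracy
        reference tracer integration to 1e-6 over 10 time units."""
        flow = AnalyticFlow.cellular(1.0, 1.0)
        x0 = np.array([1.0, 0.5])

        def rhs(t, x):
            return flow.sample_fields(x[None, :])[0][0]

        ref = integrate.solve_ivp(rhs, (0, 10.0), x0, rtol=1e-11, atol=1e-12)
        pop = single_swimmer(pos=tuple(x0), us=0.0, alpha=0.0)
        for _ in range(1000):
            pop = step_run(pop, flow, 0.01)
        assert np.abs(pop.positions[0] - ref.y[:, -1]).max() < 1e-6

    def test_orientation_norm_conserved(self, default_flow):
        """Angle storage keeps |p| = 1 exactly after many steps in flow."""
        pop = make_population(100, us=0.5, alpha=0.98)
        gf = GriddedFlow(default_flow.copy(), 128)
        for _ in range(200):
            pop = step_run(pop, gf, 0.01)
        assert np.abs(np.linalg.norm(pop.orientations, axis=1) - 1).max() < 1e-10

    def test_sphere_trajectories_independent_of_strain(self):
        """alpha=0 dynamics must not involve E: zeroing the strain field
        reproduces the trajectories exactly."""
        state = init_flow(FlowParams(seed=5, tau_f=np.inf))

        class ZeroStrain:
            periodic = True
            L = state.params.L

            def sample_fields(self, x):
                u, om, exx, exy = state.sample_fields(x)
                return u, om, np.zeros_like(exx), np.zeros_like(exy)

        pop_a = make_population(50, us=0.5, alpha=0.0, seed=3)
        pop_b = pop_a.copy()
        for _ in range(100):
            pop_a = step_run(pop_a, state, 0.01)
            pop_b = step_run(pop_b, ZeroStrain(), 0.01)
        np.testing.assert_array_equal(pop_a.positions, pop_b.positions)
        np.testing.assert_array_equal(pop_a.theta, pop_b.theta)


class TestTurns:
    def test_noiseless_reversal_is_exact(self, rng):
        pat = MotilityPattern(theta_m0=180.0, sigma=0.0)
        angles = draw_turn(pat, rng, size=100)
        assert set(np.abs(angles)) == {180.0}
        # applying a reversal flips the orientation vector
        pop = single_swimmer(theta=0.3)
        pop.tau[:] = 1e-12  # force a turn this step
        out = maybe_reorient(pop, pat, 0.01, rng)
        np.testing.assert_allclose(out.orientations[0],
                                   -single_swimmer(theta=0.3).orientations[0],
                                   atol=1e-12)

    def test_tumble_angle_statistics(self):
        """Turns are +-70 deg with N(0, 5 deg) noise: signed mean ~ 0,
        |angle| centred on 70 with std 5 within 2%."""
        rng = np.random.default_rng(11)
        pat = MotilityPattern(theta_m0=70.0, sigma=0.0)
        a = draw_turn(pat, rng, size=100_000)
        assert abs(a.mean()) < 0.7  # 3 sigma of the +-70 mixture
        assert np.all(np.abs(np.abs(a) - 70.0) < 1e-12)
        pat5 = MotilityPattern(theta_m0=70.0, sigma=5.0)
        a5 = draw_turn(pat5, rng, size=100_000)
        assert abs(np.std(np.abs(a5) - 70.0) - 5.0) < 0.1

    def test_draw_turn_requires_enabled_pattern(self, rng):
        with pytest.raises(ValueError):
            draw_turn(MotilityPattern.simple(), rng)

    def test_disabled_pattern_never_reorients(self, rng):
        pop = make_population(100, us=1.0, alpha=0.0)
        out = maybe_reorient(pop, MotilityPattern.simple(), 0.01, rng)
        np.testing.assert_array_equal(out.theta, pop.theta)

    def test_invalid_tau_rejected(self, rng):
        pop = make_population(5, us=1.0, alpha=0.0)
        pop.tau[:] = -1.0
        with pytest.raises(ValueError):
            maybe_reorient(pop, MotilityPattern.run_reverse(), 0.01, rng)

    def test_turn_frequency_matches_bernoulli_contract(self):
        """10^5 swimmer-steps at dt/tau = 0.01 -> turn count within 3 sigma."""
        rng = np.random.default_rng(21)
        pat = MotilityPattern.run_and_tumble(tau_0=1.0)
        pop = make_population(1000, us=0.0, alpha=0.0, tau_0=1.0)
        turns = 0
        for _ in range(100):
            old = pop.theta
            pop = maybe_reorient(pop, pat, 0.01, rng)
            turns += int(np.count_nonzero(pop.theta != old))
        n, p = 100 * 1000, 0.01
        assert abs(turns - n * p) < 3 * math.sqrt(n * p * (1 - p))

    def test_run_lengths_exponential(self):
        """Poisson switching: run lengths ~ Exp(tau_0) (KS test p > 0.01)."""
        rng = np.random.default_rng(31)
        pat = MotilityPattern.run_reverse(tau_0=1.0)
        n, dt, nsteps = 600, 0.01, 4000
        pop = make_population(n, us=0.0, alpha=0.0, tau_0=1.0)
        last = np.zeros(n)
        runs = []
        # runs starting in the last 10 tau_0 are skipped: recording only
        # completed runs would otherwise censor the long ones
        t_latest_start = nsteps * dt - 10.0
        for k in range(1, nsteps + 1):
            old = pop.theta
            pop = maybe_reorient(pop, pat, dt, rng)
            turned = np.nonzero(pop.theta != old)[0]
            t = k * dt
            keep = turned[last[turned] <= t_latest_start]
            runs.extend(t - last[keep] - 0.5 * dt)  # midpoint of the step
            last[turned] = t
        runs = np.asarray(runs)
        assert len(runs) > 10_000
        ks = stats.kstest(runs, "expon", args=(0, 1.0))
        assert ks.pvalue > 0.01
        assert abs(runs.mean() - 1.0) < 0.05


class TestEmergentTransport:
    def test_run_and_tumble_diffusivity_matches_closed_form(self):
        """Quiescent fluid: MSD crosses from ballistic to diffusive with
        D = us^2 tau_0 / (2 (1 - <cos theta_m>)) in 2D, within 10%."""
        us, tau_0, sigma_deg = 1.0, 1.0, 5.0
        pat = MotilityPattern.run_and_tumble(tau_0=tau_0, sigma=sigma_deg)
        rng = np.random.default_rng(41)
        n, dt, T = 3000, 0.01, 50.0
        pop = make_population(n, us=us, alpha=0.0, seed=8, tau_0=tau_0)
        x0 = pop.positions.copy()
        flow = AnalyticFlow.quiescent()
        nsteps = int(T / dt)
        ts, msd = [], []
        for k in range(1, nsteps + 1):
            pop = step_run(pop, flow, dt)
            pop = maybe_reorient(pop, pat, dt, rng)
            if k % 100 == 0:
                d = pop.positions - x0
                ts.append(k * dt)
                msd.append(np.mean((d * d).sum(axis=1)))
        ts, msd = np.asarray(ts), np.asarray(msd)
        # ballistic regime: at t = 0.1 tau_0 << tau_0, MSD ~ (us t)^2
        pop_b = make_population(n, us=us, alpha=0.0, seed=9, tau_0=tau_0)
        xb = pop_b.positions.copy()
        for _ in range(10):
            pop_b = step_run(pop_b, flow, dt)
            pop_b = maybe_reorient(pop_b, pat, dt, rng)
        msd_b = np.mean(((pop_b.positions - xb) ** 2).sum(axis=1))
        assert abs(msd_b - (us * 0.1) ** 2) < 0.1 * (us * 0.1) ** 2
        # diffusive regime: fit slope of MSD over t in [20, 50]
        sel = ts >= 20.0
        slope = np.polyfit(ts[sel], msd[sel], 1)[0]
        sigma = math.radians(sigma_deg)
        mean_cos = math.cos(math.radians(70.0)) * math.exp(-sigma * sigma / 2)
        D_theory = us * us * tau_0 / (2 * (1 - mean_cos))
        assert abs(slope / 4 - D_theory) / D_theory < 0.10

    def test_noiseless_reversal_walk_is_collinear(self):
        """run-reverse with sigma=0 in still fluid traces a 1D segment."""
        rng = np.random.default_rng(51)
        pat = MotilityPattern(theta_m0=180.0, sigma=0.0, tau_0=0.5)
        pop = single_swimmer(theta=0.77, us=1.0)
        flow = AnalyticFlow.quiescent()
        pts = []
        for _ in range(2000):
            pop = step_run(pop, flow, 0.01)
            pop = maybe_reorient(pop, pat, 0.01, rng)
            pts.append(pop.positions[0].copy())
        pts = np.asarray(pts)
        rel = pts - pts.mean(axis=0)
        # smallest singular value measures off-line scatter
        assert np.linalg.svd(rel, compute_uv=False)[-1] < 1e-8
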