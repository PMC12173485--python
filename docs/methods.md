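# Methods

This note records the model equations, the numerical schemes, the parameter
choices that matter, and the design decisions taken where the problem was
genuinely open.  Units: lengths in vortex sizes λ_f, velocities in the flow
mean speed u_f, times in the eddy turnover time t_f = λ_f/u_f; the default
non-dimensionalization is u_f′ = 1, λ_f′ = 1, τ_f′ = 2π, box side L′ = 2π
with periodic boundaries.

## Synthetic turbulent flow

The velocity field is a kinematic surrogate for dissipative-scale 2-D
turbulence: it is *prescribed*, not solved from Navier–Stokes, and is meant
to provide (only) the features the swimmer dynamics couple to — vortices of
a well-defined size and lifetime, statistically stationary, homogeneous,
isotropic and incompressible.

Construction: a stream function ψ(x, t) = Σ_k A_k(t) e^{ik·x} + c.c. over
integer wavevectors on the spectral shell |k| ∈ [k0 − hw, k0 + hw]
(defaults k0 = 2, hw = 1, all 14 half-plane shell modes used).  Velocity,
vorticity and rate of strain derive from ψ by exact spectral
differentiation, so ∇·u = 0 to machine precision and no tolerance enters
downstream orientation dynamics.

**Vortex-scale calibration.**  With the box fixed at L = 2πλ_f, the peak
wavenumber sets the ratio of the velocity-gradient timescale to the eddy
turnover time: ω_rms ≈ k0 · u_rms.  The definition of the turnover time
(2πλ_f/u_f = time for a fluid element to circle a vortex) pins the fluid
angular rate to u_f/λ_f, i.e. ω_rms/2 ≈ u_f/λ_f, giving k0 = 2 (measured
ω_rms ≈ 2.5 at k0 = 2).  A wavelength-based identification (2π/k0 = λ_f,
i.e. k0 = 6) looks natural but makes velocity gradients ~3× stronger at the
same mean speed; orientations then realign within ~0.15 t_f and the run-time
scale τ₀ ~ t_f no longer competes with the flow — the regime the model is
designed to probe.  The scale-match diagnostic
(`longitudinal_correlation_length`) is the 1/e radius of the longitudinal
velocity autocorrelation, ≈1.1 λ_f at the defaults; for this broad low-k
shell the correlation decays without a zero crossing, so an e-folding rather
than first-zero definition is used.

**Temporal model.**  Each amplitude follows an independent complex
Ornstein–Uhlenbeck process with correlation time τ_f, advanced by the
exact-in-distribution update A ← aA + √((1−a²)σ²/2)(ξ₁+iξ₂), a = e^{−Δt/τ_f}.
There is no Euler bias at any step size; τ_f = ∞ freezes the flow.  At
initialization the amplitudes are drawn i.i.d. Gaussian and rescaled so the
instantaneous spatial-mean speed equals u_f exactly; the stationary variance
σ² targeted by the OU process is the *realization's own* post-rescale
variance — targeting the ensemble value instead would inflate the long-time
energy by E[1/V̂] − 1 ≈ +13% for 14 modes (Jensen's inequality), a bias the
stationarity tests would (and originally did) catch.

**Evaluation.**  `FlowState.sample_fields` sums the modes exactly at
arbitrary points (used by all oracle tests).  Production runs use
`GriddedFlow`: per step one FFT synthesis of (u, ω, E) on an n×n grid
(spectrally exact at the nodes; Hermitian spectra let two real fields share
one complex FFT) plus periodic bilinear interpolation, with relative error
O((k_max h)²) ≈ 0.4% at n = 256.  The flow amplitudes advance once per Δt on
the same clock as the swimmers and are held during the Runge–Kutta substeps.

## Swimmers

Orientation is stored as an angle θ, which conserves |p| = 1 identically;
the angle form dθ/dt = ω/2 + α(E_xy cos 2θ − E_xx sin 2θ) is verified
against the vector form ½ω×p + α(I−pp)Ep by a property test.  Translation
and orientation advance together with classical RK4 at Δt = 0.01 t_f; the
accuracy bar is the Jeffery tumbling period in simple shear,
T = 2π(r + 1/r)/γ, reproduced to <0.1% for aspect ratios 2 and 5.  The
shape parameter is the Bretherton α = (r²−1)/(r²+1), which maps spheres to
α = 0 and keeps α < 1 as the orientation equation requires.

Turns are Bernoulli events with per-step probability min(Δt/τ, 1), at most
one per swimmer per step, applied after the continuous substep.  A turn adds
±θ_m0 (equal probability) plus N(0, σ) noise to θ, with θ_m0 = 70°
(run-and-tumble), 180° (run-reverse) or disabled (simple swimmers), σ = 5°
by default.  Run lengths are therefore exponential with mean τ (checked by
KS test); the effective diffusivity of run-and-tumble in still fluid matches
D = u_s²τ₀ / (2(1 − ⟨cos θ_m⟩)) within 10%.

## Food sources and chemoattractant

The n = 5 sources are light, small particles (Stokes number ≪ 1) advected
as tracers with the same RK4 clock.  The concentration obeys
∂C/∂t + u·∇C = −κC away from the sources (no molecular diffusion term in
the model; none is added), with the grid cell containing each source
clamped to C₀ after every step — the simplest reading of a point source of
fixed strength.  Transport is semi-Lagrangian: an RK2 midpoint back-trace
with periodic bilinear interpolation, followed by exact multiplicative
decay e^{−κΔt}.  The scheme is unconditionally stable and monotone (bilinear
weights are convex), so 0 ≤ C ≤ C₀ holds identically; with u = 0 it reduces
to exact decay.  Numerical (interpolation) diffusion is the price, and is
controlled by resolution: doubling M changes concentrations sampled along a
reference trajectory by <5% of C₀ at the default M = 256.  Before swimmers
are released, flow + sources + field are spun up for 32 τ_f, after which the
per-step change of total concentration is below 1% (source clamp balancing
decay).

## Chemotaxis

Receptor kinetics dR_b/dt = K_d/(K_d+C)² · DC/Dt and run-time law
τ = τ₀ e^{α_c dR_b/dt}, with the exponent clamped to ±50 (τ saturates rather
than overflows; in steep plumes the response is effectively bang-bang:
immediate turn when the perceived signal drops, indefinite run when it
rises).

**What "perceived" means is a genuine modelling fork.**  Two variants are
implemented:

* `swimming_only` (default): DC/Dt = ∂C/∂t + u_s p·∇C.  The swimmer senses
  the field's local evolution plus its own displacement through the field,
  but *not* the passive sweeping by the fluid — being carried along with
  the plume it is embedded in produces no signal.
* `trajectory`: the finite difference of the sampled concentration along
  the full path (advection included).

The default matters for the headline tracking comparison.  With the
`trajectory` variant, any swept-away swimmer instantly senses the loss and
turns: chemotaxis becomes a saturating gradient climber that succeeds almost
regardless of motility pattern, and run-and-tumble (whose 70° turns explore
directions faster) tracks *better* than run-reverse.  With `swimming_only`,
fluid transport is invisible to the sensor, so staying near a moving source
requires physically moving with it — which is exactly what flow-aligned
elongated reversers do and tumblers do not.  The tracking experiments in the
test suite show run-reverse (α = 0.98, u_s = u_f) reaching a time-averaged
⟨d⟩/d* about half that of run-and-tumble under identical flows, the
elongation advantage for reversers (α: 0.98 ≲ 0.75 < 0), shape-insensitivity
for tumblers, and ⟨d⟩/d* → 1 as u_s → 0.  Defaults α_c = 300, K_d/C₀ = 1,
τ₀ = 1 (the flow time unit anchored to one second); the tracking-figure
configuration uses α_c = 600.  R_b-rate is used raw — no exponential memory
kernel — and concentrations enter only as C/C₀, so only K_d/C₀ matters.

## Seeding and pairing

One master seed is split via `SeedSequence` into named streams: flow,
sources, swimmers, baseline.  Flow and source realizations depend only on
the master seed, so two runs differing only in motility pattern share the
identical environment and initial swimmer placement — pattern comparisons
are paired, not confounded by flow realization.  Runs are bit-reproducible
given the config.  One caveat: the flow stream is consumed once per step,
so runs at different Δt see different flow *paths* (same statistics); the
step-size convergence tests therefore use a frozen flow (τ_f = ∞), which
poses the same continuous problem at both step sizes.

## Observables

⟨θ_u⟩ = mean over swimmers of the unsigned angle between p and u (degrees,
[0°, 180°]; 90° for a symmetric distribution) and ⟨|cos θ_u|⟩ (1 for perfect
alignment, head and tail counted alike; 2/π ≈ 0.637 for isotropic
orientations).  Swimmers at points with |u| < 10⁻¹² carry no angle and are
excluded (and counted).  Alignment scans snapshot every 0.1 t_f after a
2 t_f transient.  Tracking uses the periodic minimum-image nearest-source
distance ⟨d⟩, normalized by d*: the Monte-Carlo mean nearest-source distance
of uniformly random points against the *same* source trajectory, recomputed
at every snapshot (for 5 uniform sources in the (2π)² box d* ≈ 1.3 λ_f; the
normalization contract is ⟨d⟩/d* = 1 for passive uniform particles, which
the u_s → 0 limit and a direct quadrature test both confirm).

## Problem sizes

Alignment experiments use 10⁴ swimmers to t = 60 t_f in the test suite and
5×10⁴ in `scripts/acceptance.py`; tracking runs use 500 swimmers, field grid
M = 128, spin-up 32 τ_f and a 60 t_f measurement window averaged from
t = 20 t_f, all at Δt = 0.01.  These sizes put the Monte-Carlo scatter of
each asserted statistic comfortably below its test tolerance while keeping
the full suite inexpensive on a single core.

## Known limitations

* The flow is a kinematic surrogate: no Navier–Stokes dynamics, no energy
  cascade, no intermittency, and a single spectral shell — quantities
  sensitive to flow microstructure inherit this approximation.
* Strictly 2-D; three-dimensional turbulence weakens elongation-induced
  clustering, so 2-D results overstate alignment effects.
* No chemoattractant diffusion (interpolation diffusion only), no source
  depletion, consumption or settling; sources never expire.
* Motility idealizations: constant swim speed (no chemokinesis), symmetric
  forward/backward speed, no run-reverse-flick, no swimmer–swimmer
  interaction, no hydrodynamic feedback on the flow.
* Within this model class, a reversal flips the sign of cos θ_u (retention
  factor cos 180° = −1) while a 70° tumble shrinks it (cos 70° ≈ +0.34), so
  the *head-tail asymmetry* of the angle histogram is systematically larger
  for run-and-tumble than for run-reverse at equal τ₀, for any
  alignment-rebuild rate — even though run-and-tumble has the weaker overall
  alignment ⟨|cos θ_u|⟩.  Orderings phrased in terms of histogram asymmetry
  should be interpreted with this in mind.
* The bang-bang regime of the run-time law (exponent clamp) makes tracking
  results insensitive to the precise α_c once saturated; α_c matters mainly
  through the threshold signal level at which saturation sets in.
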