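# Methods

## Model

The swimmer is an overdamped active Brownian sphere.  Its position
**r** and orientation unit vector **n** (the patch axis) evolve as

    dr/dt = V(β) n + u_flow + sqrt(2 D_t) ξ(t)
    dn/dt = sqrt(2 D_r) η(t) × n        (Stratonovich sense; |n| = 1)

with Stokes–Einstein coefficients D_t = k_B T/(6πηR) and
D_r = k_B T/(8πηR³).  The phoretic angular velocity is set to zero: for
these vesicles Brownian rotation dominates any slip-flow torque, so
reorientation is purely diffusive.  Propulsion is *orientation-gated*:

    V(β) = V0_local · (cos β/2)^p ,   p = nint(2π/α),

where β is the angle between **n** and the local up-gradient direction
and α = 2 arcsin(r_patch/R) is the sector angle of the permeable patch.
In gated mode the local amplitude is V0_local = min(V_cap, χ|∇C|): the
product efflux — and hence the phoretic slip — scales with the local
substrate gradient, with χ a chemotactic mobility (speed per unit
gradient) that is a free calibration parameter, saturated at a cap.  In
constant-speed mode V = V0 regardless of the field (the textbook active
Brownian particle, used for effective-diffusion calculations).

Two closed forms anchor the simulator:

* constant speed: D_eff = D_t + v²/(6 D_r) at lag times ≫ 1/D_r;
* gated, uniform gradient, isotropic orientations: mean drift along the
  gradient = V0 · 2p/((p+2)(p+4)), which is V0·5/42 for p = 10.  The
  orientation distribution stays isotropic because gating affects
  translation only.

Both identities are enforced by tests against the stochastic integrator.

## Conventions

* Reorientation time τ = 1/D_r.  For R = 50 nm in water at 37 °C
  (η = 0.69 mPa·s, read as mPa·s where the unit is elided) this gives
  τ = 0.506 ms, the ~0.5 ms orientation-memory scale of the system.
* Péclet number Pe = 2Rv/D_t (particle diameter as the advective
  length); this convention reproduces Pe = 0.15 and 2.3 for 10 and
  150 μm/s flows past the 50 nm vesicle.
* Units: μm, s internally; radii accepted in nm; 37 °C = 310.15 K.
* nint rounds ties half away from zero.

## Numerical integration

Euler–Maruyama with default dt = 1/30000 s (≈ 33 μs, τ_r/15 for the
reference swimmer; configs refuse dt > τ_r/10).  The orientation update
is a geodesic rotation: a 2D Gaussian tangent displacement of standard
deviation sqrt(2 D_r dt) per component is applied as a great-circle
step.  This preserves |n| = 1 exactly and reproduces the
autocorrelation ⟨n(t)·n(0)⟩ = exp(−2 D_r t) to O(dt²); the simpler
add-and-renormalise update was rejected because at dt = τ_r/15 it
inflates the orientation correlation time by several percent, which
feeds directly into D_eff.  Gaussian noise comes from NumPy's PCG64
streams, generated in bounded chunks and consumed by numba-compiled
kernels; per-run child seeds derive from one master seed via
SeedSequence, so every result is reproducible from (config, seed).

Camera sampling thins the recorded positions to the frame interval and
drops z, mimicking 2D NTA projections; the integration step must tile
the frame interval (1000 steps per frame at 30 fps).

## Substrate fields

* `linear` — constant ∇C, the quasi-steady state once an injected
  substrate front has swept the field of view (concentration clamped at
  zero, gradient zero where clamped).
* `diffusive_1d` — C(s,t) = C0 erfc(s/(2√(D_s(t−t₀)))) from a plane
  held at C0, with the analytic gradient; zero before the start time,
  clamped to C0 behind the source.
* `radial_disk` — the same erfc form in the radial coordinate outside a
  disk source (an agarose plug in a dish).

Glucose diffusivity defaults to 600 μm²/s (literature value for water
at body temperature).  Substrate consumption by the swimmers is not
modelled.

## Patch product-distribution oracle

The steady product cloud around the patch is approximated by tiling the
spherical cap with ≥100 equal point sources (deterministic Fibonacci
lattice, uniform in solid angle) of free-space steady-diffusion kernels
∝ 1/distance, summed on a shell at R + offset and normalised to 1 at
β = 0.  No vesicle-surface boundary condition or substrate depletion is
imposed.  The evaluation offset is the kernel's one free parameter:
near the membrane the profile collapses to the sharp patch footprint,
far away to a monopole.  The default, r_patch/2 (7.5 nm for the
reference geometry), is the distance over which the patch near-field
smooths out; there the profile is captured by the analytic gating law,
and the least-squares exponent (9.63) rounds to the geometric p = 10.
This consistency — numerical cloud vs analytic gating law — is what the
oracle is for; the absolute concentration scale linking product density
to speed is not available, which is why V0 is inferred from data rather
than predicted.

## Synthetic NTA acquisition

The generator emulates the acquisition protocol: 30 fps, recordings up
to 60 s, thousands of tracks, isotropic Gaussian localization noise
(default σ = 20 nm, a typical NTA precision), independent per-frame
detection dropout that fragments tracks, and a 1 s minimum-duration
filter.  Localization noise leaves the fitted MSD slope unbiased and
raises the intercept by 4σ²; dropout fragment statistics follow the
Bernoulli run-length law — both are verified against closed forms.  Not
emulated: scattering-intensity/size-dependent detectability, linking
errors between nearby particles, instrument drift correction.  Passing
tests therefore show estimator correctness under the modelled noise
processes, not robustness to every instrument artefact.

## Trajectory statistics

* MSD: per-track time average with overlapping windows, then an
  unweighted mean over tracks (tracks are analysed over a fixed 1 s
  window, so length weighting is deliberately not applied); SE across
  tracks.  Frame gaps contribute the pairs that exist.
* Diffusive fit: OLS slope/4 over lags ≤ ⅓ of the maximum (configurable)
  with a free intercept absorbing the noise offset.  Because MSD values
  at different lags are strongly correlated, `estimate_diffusion`
  provides an honest SE by splitting tracks into groups and fitting per
  group.
* Ballistic fit: non-negative least squares of 4Dτ + (v_d τ)²;
  negative-curvature fits are clipped to v_d = 0 and flagged.
* Classification: log-log slope s over the positive lags; Fickian for
  s ∈ [0.9, 1.1], superdiffusive for s ≥ 1.25, else indeterminate.  The
  1.25 threshold was chosen so passive sampling noise rarely leaves the
  Fickian band (verified over 50 seeded replicates).
* Drift: signed projection of per-track net displacement on the
  gradient unit vector per time bin (a vector projection, so opposing
  motion subtracts); SE across tracks.
* Propulsion inference: for each candidate V0 a gated ensemble is
  simulated under the acquisition protocol and compared to the observed
  MSD by mean squared relative deviation; the minimiser is the
  estimate.  The min/max range refits 200 bootstrap track resamples
  against the same candidate curves (the bootstrap implements the
  min/max uncertainty bars; the original protocol for those bars is
  not specified anywhere, so this is the package's choice).

## Capillary binding model

Cylinder of radius 4 μm and length 800 μm, Poiseuille profile
u(ρ) = 2ū(1 − ρ²/a²) with ū defaulting to 1000 μm/s (typical capillary
speed; configurable — absolute bound fractions are sensitive to it),
sticky walls (irreversible binding at centre-to-wall distance = particle
radius), particles seeded uniformly over the entrance disk.  The
glucose gradient is taken radially outward with constant effective
amplitude, parameterized directly by the wall propulsion speed.
Erythrocytes and margination are excluded; hematocrit is metadata.
Within this simplification the bound fraction rises with propulsion
speed for every size and the 250 nm / 200 μm/s arm binds ≥90% of
particles; the size ordering at maximal propulsion appears as
saturation near 100% rather than a strict size advantage, because the
red-cell-induced near-wall excess that favours large particles in real
vessels has no counterpart here.

## Problem sizes

Defaults used by the test suite and the acceptance script were chosen
as the smallest ensembles whose standard errors make the assertions
meaningful: 2000–2500 trajectories for D_eff ratios (SE ≈ 1–2% of the
ratio), 5000 particles for 3-SE drift and autocorrelation checks, 50
seeds for classification rates, 20 round-trip repetitions with
2000-track datasets for inference coverage, and 400–1200 paired-seed
particles per capillary arm.

## Known limitations

Hydrodynamic wall effects, swimmer–swimmer interactions, oxygen-bubble
formation, vesicle dissolution and receptor-level binding kinetics are
outside the model.  The literal slip-velocity surface integrals are not
computed — propulsion is parameterized, consistent with neglecting the
phoretic torque.  Measured enzyme loadings of specific preparations
require the corresponding chromatography/light-scattering inputs and
are not reproduced by the loading arithmetic alone.
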