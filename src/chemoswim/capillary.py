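"""Simplified capillary wall-binding model for chemotactic nanoparticles.

An agent-based picture of nanoparticles traversing a microvessel:
Poiseuille advection along the axis, Brownian translation and rotation,
and orientation-gated chemotactic propulsion directed up a radial
substrate gradient (blood glucose is taken to increase toward the
vessel wall).  The walls are no-slip, sticky boundaries: a particle
whose centre approaches within one particle radius of the wall binds
irreversibly; everything else exits at the end of the vessel.

Erythrocytes are deliberately absent — margination by red blood cells
is not modelled — so the recorded hematocrit is metadata only and the
bound fractions are to be read as a qualitative sweep (monotonicity in
propulsion speed and in particle size), not as blood-accurate numbers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import physics
from ._kernels import integrate_capillary
from .errors import ParameterError, StepSizeError
from .physics import Medium
from .swimmer import SwimmerGeometry

#: Default mean blood speed in a capillary, μm/s (typical literature value).
DEFAULT_MEAN_FLOW_UM_S = 1000.0


@dataclass(frozen=True)
class CapillaryScenario:
    """One arm of the binding sweep."""

    vessel_radius_um: float = 4.0
    vessel_length_um: float = 800.0
    mean_flow_um_s: float = DEFAULT_MEAN_FLOW_UM_S
    hematocrit_pct: float = 10.7  # metadata only; erythrocytes are not simulated
    particle_radius_nm: float = 50.0
    propulsion_um_s: float = 0.0
    gating_exponent: int = 10
    n_particles: int = 100
    medium: Medium = field(default_factory=Medium)
    dt_s: float = 1.0 / 30000.0
    max_transit_factor: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.vessel_radius_um * 1e3 <= self.particle_radius_nm:
            raise ParameterError("vessel radius must exceed the particle radius")
        if self.n_particles < 1:
            raise ParameterError("n_particles must be >= 1")
        if self.propulsion_um_s < 0 or self.mean_flow_um_s < 0:
            raise ParameterError("speeds must be non-negative")
        tau_r = physics.diffusion_set(self.medium, self.particle_radius_nm).tau_r_s
        if self.dt_s > tau_r / 10.0:
            raise StepSizeError(
                f"dt = {self.dt_s:g} s exceeds tau_r/10 = {tau_r / 10:g} s")


@dataclass(frozen=True)
class BindingResult:
    """Outcome of one capillary passage simulation."""

    bound_fraction: float
    se: float
    n_bound: int
    n_exited: int
    bind_positions_um: np.ndarray

    @property
    def n_total(self) -> int:
        return self.n_bound + self.n_exited


def poiseuille_velocity(scenario: CapillaryScenario, radial_position_um) -> np.ndarray:
    """Axial speed u(ρ) = 2 ū (1 − ρ²/a²) of the parabolic vessel flow."""
    rho = np.asarray(radial_position_um, dtype=float)
    a = scenario.vessel_radius_um
    if np.any(rho < 0) or np.any(rho > a):
        raise ParameterError("radial position must lie in [0, vessel radius]")
    return 2.0 * scenario.mean_flow_um_s * (1.0 - rho**2 / a**2)


def simulate_capillary(scenario: CapillaryScenario) -> BindingResult:
    """Single passage of an ensemble through the sticky-walled vessel.

    Particles are seeded uniformly over the entrance cross-section
    (excluding the contact shell, where they would bind instantly).  The
    chemotactic propulsion amplitude is parameterized directly by the
    effective wall speed ``propulsion_um_s``; its direction follows the
    particle orientation, gated by the angle to the outward radial
    gradient.  The bound fraction carries a binomial standard error.
    """
    d = physics.diffusion_set(scenario.medium, scenario.particle_radius_nm)
    sig_t = math.sqrt(2.0 * d.D_t_um2_s * scenario.dt_s)
    sig_r = math.sqrt(2.0 * d.D_r_rad2_s * scenario.dt_s)
    contact_um = scenario.particle_radius_nm * 1e-3
    seed_max = scenario.vessel_radius_um - contact_um

    ss = np.random.SeedSequence(scenario.seed)
    s_entry, s_kernel = [int(s % (2**31)) for s in ss.generate_state(2, dtype=np.uint64)]
    rng = np.random.default_rng(s_entry)
    # uniform over the entrance disk
    rho = seed_max * np.sqrt(rng.random(scenario.n_particles))
    phi = rng.random(scenario.n_particles) * 2.0 * math.pi
    y0 = rho * np.cos(phi)
    z0 = rho * np.sin(phi)

    if scenario.vessel_length_um <= 0:
        return BindingResult(0.0, 0.0, 0, scenario.n_particles, np.empty(0))

    transit = scenario.vessel_length_um / max(scenario.mean_flow_um_s, 1e-9)
    max_steps = int(min(scenario.max_transit_factor * transit / scenario.dt_s, 5e6))
    fates, bind_x = integrate_capillary(
        y0, z0, scenario.n_particles, scenario.dt_s, sig_t, sig_r,
        scenario.vessel_radius_um, scenario.vessel_length_um,
        scenario.mean_flow_um_s, contact_um, scenario.propulsion_um_s,
        scenario.gating_exponent / 2.0, max_steps, s_kernel,
    )
    n_bound = int((fates == 1).sum())
    n = scenario.n_particles
    frac = n_bound / n
    se = math.sqrt(frac * (1.0 - frac) / n)
    return BindingResult(frac, se, n_bound, n - n_bound,
                         bind_x[np.isfinite(bind_x)])


def binding_sweep(radii_nm=(50.0, 100.0, 250.0),
                  speeds_um_s=(0.0, 50.0, 100.0, 150.0, 200.0),
                  template: CapillaryScenario | None = None,
                  n_seeds: int = 1) -> pd.DataFrame:
    """Full factorial (radius × propulsion speed) sweep with shared seeds.

    Every arm reuses the same seed set so that comparisons across arms
    are paired.  Returns a tidy table with one row per arm:
    ``radius_nm, speed_um_s, bound_fraction, se, n, seed_set``.
    """
    if len(radii_nm) == 0 or len(speeds_um_s) == 0:
        raise ParameterError("radius and speed grids must be non-empty")
    if template is None:
        template = CapillaryScenario()
    rows = []
    seed_set = [template.seed + k for k in range(n_seeds)]
    for R in radii_nm:
        for v in speeds_um_s:
            bound = 0
            total = 0
            for s in seed_set:
                sc = replace(template, particle_radius_nm=float(R),
                             propulsion_um_s=float(v), seed=s)
                res = simulate_capillary(sc)
                bound += res.n_bound
                total += res.n_total
            frac = bound / total
            rows.append({
                "radius_nm": float(R),
                "speed_um_s": float(v),
                "bound_fraction": frac,
                "se": math.sqrt(frac * (1 - frac) / total),
                "n": total,
                "seed_set": ",".join(str(s) for s in seed_set),
            })
    return pd.DataFrame(rows)
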