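"""Stochastic simulation of ensembles of chemotactic vesicles.

The equations of motion are the overdamped Langevin pair for an active
Brownian sphere: the position advances with the propulsion velocity
``V(beta) n`` plus ambient flow plus translational Brownian noise, and
the orientation unit vector ``n`` diffuses on the sphere with rotational
diffusivity ``D_r``.  The phoretic angular velocity is neglected — for
these vesicles it is small against Brownian rotation — so reorientation
is purely diffusive.

Propulsion modes
----------------
constant
    ``V = V0`` along ``n`` regardless of the field: the textbook active
    Brownian particle, used for effective-diffusion calculations.
gated
    ``V = min(V_cap, chi |grad C|) * cos(beta/2)^p`` with ``beta`` the
    angle between ``n`` and the local up-gradient direction.  ``chi`` is
    the chemotactic mobility (speed per unit gradient); in a uniform
    gradient strong enough to saturate the cap the local speed is simply
    ``V0 = V_cap`` modulated by orientation.

Camera sampling: :func:`project_to_tracks` drops the z coordinate and
thins to the acquisition frame rate, mimicking nanoparticle tracking
analysis, which records 2D projections of the 3D motion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterator

import numpy as np
import pandas as pd

from . import physics
from ._kernels import integrate_dish, step_free_chunk
from .errors import DataError, GeometryError, ParameterError, StepSizeError
from .fields import FlowField, SubstrateField
from .physics import Medium
from .swimmer import PropulsionLaw, SwimmerGeometry

#: Default integration step: 1/1000 of the 30-fps frame interval (~33 μs),
#: about τ_r/15 for a 50 nm vesicle in water at 37 °C.
DEFAULT_DT_S = 1.0 / 30000.0

TRACK_COLUMNS = ["track_id", "frame", "time_s", "x_um", "y_um"]


@dataclass(frozen=True)
class SimulationConfig:
    """Full description of one ensemble simulation."""

    medium: Medium = field(default_factory=Medium)
    geometry: SwimmerGeometry = field(default_factory=SwimmerGeometry)
    law: PropulsionLaw = field(default_factory=lambda: PropulsionLaw(0.0))
    substrate: SubstrateField = field(default_factory=SubstrateField)
    flow: FlowField = field(default_factory=FlowField)
    #: chemotactic mobility chi, (μm/s) per (mol/L/μm); None = constant-speed mode
    chemotactic_mobility: float | None = None
    n_particles: int = 1000
    dt_s: float = DEFAULT_DT_S
    duration_s: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_particles < 1:
            raise ParameterError("n_particles must be >= 1")
        if not (self.dt_s > 0):
            raise ParameterError("dt must be positive")
        if self.duration_s < self.dt_s:
            raise ParameterError("duration must be at least one step")
        tau_r = physics.diffusion_set(self.medium, self.geometry.R_nm).tau_r_s
        if self.dt_s > tau_r / 10.0:
            raise StepSizeError(
                f"dt = {self.dt_s:g} s exceeds tau_r/10 = {tau_r / 10.0:g} s "
                f"for R = {self.geometry.R_nm} nm; refine the step"
            )

    @property
    def gated(self) -> bool:
        return self.chemotactic_mobility is not None

    def diffusion(self) -> physics.DiffusionSet:
        return physics.diffusion_set(self.medium, self.geometry.R_nm)


def gated_config(V0_um_s: float, gradient_direction=(1.0, 0.0, 0.0),
                 **overrides) -> SimulationConfig:
    """Convenience: gated propulsion at saturated speed V0 in a uniform gradient.

    Builds a linear substrate field whose gradient saturates the speed cap,
    so the local propulsion amplitude is exactly ``V0`` and only the
    orientation gating modulates it — the configuration behind the
    steady-state chemotaxis experiments once the gradient is quasi-linear.
    """
    substrate = SubstrateField(
        kind="linear", C0=1.0, direction=tuple(gradient_direction),
        gradient_M_per_um=1.0,
    )
    geometry = overrides.pop("geometry", SwimmerGeometry())
    law = PropulsionLaw.from_geometry(geometry, V0_um_s)
    return SimulationConfig(
        geometry=geometry, law=law, substrate=substrate,
        chemotactic_mobility=V0_um_s,  # chi*|g| = V0 >= cap -> saturated
        **overrides,
    )


@dataclass(frozen=True)
class Trajectory3D:
    """One particle's recorded path: times, positions (μm), orientations."""

    particle_id: int
    times_s: np.ndarray
    positions_um: np.ndarray
    orientations: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.diff(self.times_s) <= 0):
            raise DataError("times must be strictly increasing")
        norms = np.linalg.norm(self.orientations, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-9):
            raise DataError("orientations must be unit vectors")


class EnsembleResult:
    """Recorded trajectories of a simulated ensemble (array-of-particles form)."""

    def __init__(self, config: SimulationConfig, times_s: np.ndarray,
                 positions_um: np.ndarray, orientations: np.ndarray) -> None:
        self.config = config
        self.times_s = times_s
        self.positions_um = positions_um
        self.orientations = orientations

    @property
    def n_particles(self) -> int:
        return self.positions_um.shape[0]

    def trajectories(self) -> Iterator[Trajectory3D]:
        for i in range(self.n_particles):
            yield Trajectory3D(i, self.times_s, self.positions_um[i],
                               self.orientations[i])


def _spawn_seeds(seed: int, n: int) -> list[int]:
    """Deterministic 31-bit child seeds from one master seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s % (2**31)) for s in ss.generate_state(n, dtype=np.uint64)]


def random_orientations(n: int, rng: np.random.Generator) -> np.ndarray:
    v = rng.standard_normal((n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def simulate_ensemble(config: SimulationConfig, record_stride: int = 1,
                      initial_positions: np.ndarray | None = None,
                      t_start_s: float = 0.0) -> EnsembleResult:
    """Integrate the ensemble and record every ``record_stride`` steps.

    Deterministic for a fixed config seed.  The initial state (record 0)
    is included; orientations start isotropic, positions at the origin
    unless given.
    """
    if record_stride < 1:
        raise ParameterError("record_stride must be >= 1")
    seeds = _spawn_seeds(config.seed, 2)
    rng = np.random.default_rng(seeds[0])
    noise_rng = np.random.default_rng(seeds[1])
    n = config.n_particles
    if initial_positions is None:
        pos0 = np.zeros((n, 3))
    else:
        pos0 = np.asarray(initial_positions, dtype=float).reshape(n, 3).copy()
    ori0 = random_orientations(n, rng)
    d = config.diffusion()
    n_steps = int(round(config.duration_s / config.dt_s))
    sig_t = math.sqrt(2.0 * d.D_t_um2_s * config.dt_s)
    sig_r = math.sqrt(2.0 * d.D_r_rad2_s * config.dt_s)
    fx, fy, fz = config.flow.vector()
    chi = config.chemotactic_mobility or 0.0
    fp = config.substrate.pack()
    code = config.substrate.code
    p_half = config.law.exponent / 2.0
    v_cap = config.law.V0_um_s

    x, y, z = pos0[:, 0].copy(), pos0[:, 1].copy(), pos0[:, 2].copy()
    nx, ny, nz = ori0[:, 0].copy(), ori0[:, 1].copy(), ori0[:, 2].copy()
    n_rec = n_steps // record_stride + 1
    times = np.empty(n_rec)
    P = np.empty((n, n_rec, 3))
    O = np.empty((n, n_rec, 3))
    times[0] = t_start_s
    P[:, 0, 0], P[:, 0, 1], P[:, 0, 2] = x, y, z
    O[:, 0, 0], O[:, 0, 1], O[:, 0, 2] = nx, ny, nz
    # noise is generated in chunks of at most ~2e7 values to bound memory
    max_chunk = max(1, int(2e7) // (n * 6))
    done = 0
    rec = 1
    while rec < n_rec:
        todo = min(record_stride, n_steps - done)
        while todo > 0:
            csteps = min(todo, max_chunk)
            noise = noise_rng.standard_normal((csteps, n, 6))
            step_free_chunk(x, y, z, nx, ny, nz, noise,
                            t_start_s + done * config.dt_s, config.dt_s,
                            sig_t, sig_r, fx, fy, fz, code, fp,
                            chi, v_cap, p_half, config.gated)
            done += csteps
            todo -= csteps
        times[rec] = t_start_s + done * config.dt_s
        P[:, rec, 0], P[:, rec, 1], P[:, rec, 2] = x, y, z
        O[:, rec, 0], O[:, rec, 1], O[:, rec, 2] = nx, ny, nz
        rec += 1
    return EnsembleResult(config, times, P, O)


def project_to_tracks(result: EnsembleResult, fps: float,
                      duration_s: float | None = None) -> pd.DataFrame:
    """2D camera sampling of a simulated ensemble.

    Drops z, thins the recorded samples to the frame interval 1/fps and
    assigns integer frame indices.  The recorded sampling interval must
    tile the frame interval exactly.
    """
    times = result.times_s
    rec_dt = times[1] - times[0] if times.size > 1 else None
    if rec_dt is None:
        raise DataError("ensemble has a single record; nothing to project")
    if duration_s is None:
        duration_s = times[-1] - times[0]
    if duration_s > times[-1] - times[0] + 1e-12:
        raise DataError(
            f"requested duration {duration_s} s exceeds simulated {times[-1] - times[0]} s"
        )
    frame_dt = 1.0 / fps
    if fps * duration_s < 1.0:
        raise ParameterError("need at least 2 frames: fps * duration >= 1")
    stride = frame_dt / rec_dt
    if abs(stride - round(stride)) > 1e-6:
        raise ParameterError(
            f"frame interval 1/fps = {frame_dt:g} s is not a multiple of the "
            f"recorded sampling interval {rec_dt:g} s"
        )
    stride = int(round(stride))
    n_frames = int(math.floor(duration_s * fps + 1e-9)) + 1
    idx = np.arange(n_frames) * stride
    if idx[-1] >= times.size:
        raise DataError("not enough recorded samples for the requested duration")
    frames = np.arange(n_frames)
    tables = []
    for i in range(result.n_particles):
        xy = result.positions_um[i, idx, :2]
        tables.append(pd.DataFrame({
            "track_id": i,
            "frame": frames,
            "time_s": frames * frame_dt,
            "x_um": xy[:, 0],
            "y_um": xy[:, 1],
        }))
    return pd.concat(tables, ignore_index=True)


def simulate_tracks(config: SimulationConfig, fps: float = 30.0,
                    duration_s: float | None = None) -> pd.DataFrame:
    """Simulate and camera-sample in one call, recording only at frames.

    The integration step must tile the frame interval; with the default
    dt of 1/30000 s and 30 fps each frame spans exactly 1000 steps.
    """
    frame_dt = 1.0 / fps
    stride = frame_dt / config.dt_s
    if abs(stride - round(stride)) > 1e-6:
        raise ParameterError("1/fps must be a multiple of dt")
    if duration_s is not None and duration_s != config.duration_s:
        config = replace(config, duration_s=duration_s)
    result = simulate_ensemble(config, record_stride=int(round(stride)))
    return project_to_tracks(result, fps)


def dish_scenario(config: SimulationConfig, dish_radius_um: float,
                  release_point_um=(0.0, 0.0), grid_n: int = 25,
                  sample_times_s=(0.0, 600.0)) -> dict:
    """Agent simulation in a petri dish with a disk substrate source.

    Vesicles are released at ``release_point`` in a dish with reflecting
    walls; the substrate field must be ``radial_disk`` (or ``none`` for
    passive controls).  Particle positions are histogrammed on a square
    ``grid_n x grid_n`` grid covering the dish at each sample time and
    normalised by the total particle count, so each map integrates to 1.

    Returns a dict with ``maps`` (time, gy, gx), ``grid_edges_um``,
    ``sample_times_s`` and ``counts`` (raw per-map totals).
    """
    if config.substrate.kind not in ("radial_disk", "none"):
        raise ParameterError("dish scenario requires a radial_disk (or none) substrate")
    if config.substrate.kind == "radial_disk":
        src = np.asarray(config.substrate.source_position, dtype=float)[:2]
        if np.linalg.norm(src) > dish_radius_um + config.substrate.source_radius_um:
            raise GeometryError("substrate source lies outside the dish")
    rp = np.asarray(release_point_um, dtype=float)
    if np.linalg.norm(rp) >= dish_radius_um:
        raise GeometryError("release point outside the dish")

    seeds = _spawn_seeds(config.seed, 2)
    rng = np.random.default_rng(seeds[0])
    n = config.n_particles
    pos0 = np.tile(rp, (n, 1))
    ori0 = random_orientations(n, rng)
    d = config.diffusion()
    n_steps = int(round(config.duration_s / config.dt_s))
    rec_steps = np.unique(np.clip(
        np.round(np.asarray(sample_times_s, dtype=float) / config.dt_s), 0, n_steps
    ).astype(np.int64))
    if rec_steps[0] == 0:
        rec_steps = rec_steps[1:]  # the t=0 snapshot is the release point itself
        include_t0 = True
    else:
        include_t0 = False
    sig_t = math.sqrt(2.0 * d.D_t_um2_s * config.dt_s)
    sig_r = math.sqrt(2.0 * d.D_r_rad2_s * config.dt_s)
    chi = config.chemotactic_mobility or 0.0
    P = integrate_dish(
        pos0, ori0, n_steps, config.dt_s, sig_t, sig_r,
        config.substrate.code, config.substrate.pack(),
        chi, config.law.V0_um_s, config.law.exponent / 2.0, config.gated,
        dish_radius_um, rec_steps, seeds[1],
    )
    snapshots = [pos0[:, :2]] if include_t0 else []
    snapshots += [P[:, k, :] for k in range(rec_steps.size)]
    edges = np.linspace(-dish_radius_um, dish_radius_um, grid_n + 1)
    maps = []
    counts = []
    for snap in snapshots:
        H, _, _ = np.histogram2d(snap[:, 0], snap[:, 1], bins=(edges, edges))
        counts.append(int(H.sum()))
        maps.append(H.T / n)
    times_out = ([0.0] if include_t0 else []) + [k * config.dt_s for k in rec_steps]
    return {
        "maps": np.array(maps),
        "counts": np.array(counts),
        "grid_edges_um": edges,
        "sample_times_s": np.array(times_out),
    }
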