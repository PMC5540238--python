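"""Stochastic integrator: passive limits, rotational diffusion, gating, flow."""

import math

import numpy as np
import pytest

from chemoswim.analysis import compute_msd, fit_linear_msd
from chemoswim.errors import DataError, ParameterError, StepSizeError
from chemoswim.fields import FlowField, SubstrateField
from chemoswim.physics import diffusion_set
from chemoswim.simulate import (SimulationConfig, dish_scenario, gated_config,
                                project_to_tracks, simulate_ensemble,
                                simulate_tracks)
from chemoswim.swimmer import PropulsionLaw


class TestConfigValidation:
    def test_coarse_step_refused(self):
        with pytest.raises(StepSizeError):
            SimulationConfig(dt_s=1e-3)  # tau_r ~ 0.5 ms for the 50 nm default

    def test_bad_particle_count(self):
        with pytest.raises(ParameterError):
            SimulationConfig(n_particles=0)

    def test_duration_shorter_than_step(self):
        with pytest.raises(ParameterError):
            SimulationConfig(duration_s=1e-6)


class TestPassiveLimit:
    def test_3d_msd_slope(self):
        # V0 = 0: ensemble MSD(tau) = 6 D_0 tau in 3D
        cfg = SimulationConfig(n_particles=2000, duration_s=0.01, seed=101)
        res = simulate_ensemble(cfg, record_stride=60)
        d = cfg.diffusion()
        disp = res.positions_um - res.positions_um[:, :1]
        msd = (disp**2).sum(axis=2)
        lag = res.times_s[1:]
        mean = msd[:, 1:].mean(axis=0)
        se = msd[:, 1:].std(axis=0, ddof=1) / math.sqrt(cfg.n_particles)
        expected = 6.0 * d.D_t_um2_s * lag
        assert np.all(np.abs(mean - expected) < 3.0 * se)

    def test_projected_2d_msd_slope(self, passive_tracks, body_medium):
        from chemoswim.analysis import estimate_diffusion
        D, se = estimate_diffusion(passive_tracks)
        d = diffusion_set(body_medium, 50.0)
        assert abs(D - d.D_t_um2_s) < 3.0 * se


class TestOrientationDynamics:
    def test_unit_norm_at_all_times(self):
        cfg = SimulationConfig(n_particles=50, duration_s=0.005, seed=7)
        res = simulate_ensemble(cfg, record_stride=1)
        norms = np.linalg.norm(res.orientations, axis=2)
        assert np.all(np.abs(norms - 1.0) < 1e-9)

    def test_autocorrelation_decay(self):
        # <n(t).n(0)> = exp(-2 D_r t) within 3 SE
        cfg = SimulationConfig(n_particles=5000, duration_s=0.001, seed=8)
        res = simulate_ensemble(cfg, record_stride=5)
        d = cfg.diffusion()
        corr = (res.orientations * res.orientations[:, :1]).sum(axis=2)
        mean = corr.mean(axis=0)
        se = corr.std(axis=0, ddof=1) / math.sqrt(cfg.n_particles)
        expected = np.exp(-2.0 * d.D_r_rad2_s * res.times_s)
        assert np.all(np.abs(mean[1:] - expected[1:]) < 3.0 * se[1:])


class TestGatedPropulsion:
    def test_drift_matches_orientation_integral(self):
        # steady drift of an isotropic gated ensemble = V0 * 5/42 for p = 10
        cfg = gated_config(168.0, n_particles=5000, duration_s=0.2, seed=9)
        res = simulate_ensemble(cfg, record_stride=6000)
        vx = (res.positions_um[:, -1, 0] - res.positions_um[:, 0, 0]) / 0.2
        drift = vx.mean()
        se = vx.std(ddof=1) / math.sqrt(cfg.n_particles)
        assert abs(drift - 168.0 * 5.0 / 42.0) < 3.0 * se

    def test_zero_gradient_means_no_propulsion(self):
        # gating enabled but no field: displacement is purely Brownian
        cfg = SimulationConfig(law=PropulsionLaw(200.0, 10),
                               chemotactic_mobility=1.0,
                               n_particles=500, duration_s=0.02, seed=10)
        res = simulate_ensemble(cfg, record_stride=600)
        d = cfg.diffusion()
        msd = ((res.positions_um[:, -1] - res.positions_um[:, 0])**2).sum(axis=1)
        se = msd.std(ddof=1) / math.sqrt(cfg.n_particles)
        assert abs(msd.mean() - 6 * d.D_t_um2_s * 0.02) < 3 * se

    def test_flow_adds_vectorially(self):
        # mean velocity = flow + chemotactic drift (gradient along +x, flow +y)
        flow = FlowField(kind="uniform", velocity_um_s=(0.0, 30.0, 0.0))
        cfg = gated_config(168.0, n_particles=3000, duration_s=0.1, seed=11,
                           flow=flow)
        res = simulate_ensemble(cfg, record_stride=3000)
        v = (res.positions_um[:, -1] - res.positions_um[:, 0]) / 0.1
        se = v.std(axis=0, ddof=1) / math.sqrt(cfg.n_particles)
        assert abs(v[:, 0].mean() - 20.0) < 3 * se[0]
        assert abs(v[:, 1].mean() - 30.0) < 3 * se[1]


class TestProjection:
    def test_frame_count(self):
        cfg = SimulationConfig(n_particles=3, duration_s=1.0, seed=1)
        tracks = simulate_tracks(cfg, fps=30.0)
        assert (tracks.groupby("track_id").size() == 31).all()

    def test_straight_z_run_is_stationary_in_2d(self):
        cfg = SimulationConfig(n_particles=2, duration_s=0.01, seed=1)
        res = simulate_ensemble(cfg, record_stride=30)
        # overwrite with a synthetic straight run along z
        res.positions_um[:] = 0.0
        res.positions_um[:, :, 2] = np.linspace(0, 5, res.times_s.size)
        tracks = project_to_tracks(res, fps=250.0)
        assert np.allclose(tracks[["x_um", "y_um"]], 0.0)

    def test_duration_beyond_simulation_rejected(self):
        cfg = SimulationConfig(n_particles=2, duration_s=0.01, seed=1)
        res = simulate_ensemble(cfg, record_stride=30)
        with pytest.raises(DataError):
            project_to_tracks(res, fps=300.0, duration_s=1.0)

    def test_deterministic_for_fixed_seed(self):
        cfg = SimulationConfig(n_particles=20, duration_s=0.01, seed=123)
        a = simulate_tracks(cfg, fps=300.0)
        b = simulate_tracks(cfg, fps=300.0)
        assert a.equals(b)


class TestDishScenario:
    SOURCE = SubstrateField(kind="radial_disk", C0=1.0,
                            source_position=(50.0, 0.0), source_radius_um=10.0)

    def test_passive_release_stays_centred(self):
        cfg = SimulationConfig(substrate=self.SOURCE, law=PropulsionLaw(0.0),
                               n_particles=400, duration_s=0.5, seed=21)
        out = dish_scenario(cfg, dish_radius_um=50.0, sample_times_s=(0.0, 0.5))
        edges = out["grid_edges_um"]
        centers = (edges[:-1] + edges[1:]) / 2.0
        final = out["maps"][-1]
        com_x = (final.sum(axis=0) * centers).sum() / final.sum()
        # passive spread only: centre of mass stays near the release point
        sigma_com = math.sqrt(2 * cfg.diffusion().D_t_um2_s * 0.5 / 400)
        assert abs(com_x) < 4.0 * sigma_com + (edges[1] - edges[0]) / 2.0

    def test_chemotactic_release_drifts_to_source(self):
        cfg = SimulationConfig(substrate=self.SOURCE, law=PropulsionLaw(50.0, 10),
                               chemotactic_mobility=1e5, n_particles=400,
                               duration_s=0.5, seed=21)
        out = dish_scenario(cfg, dish_radius_um=50.0, sample_times_s=(0.0, 0.5))
        edges = out["grid_edges_um"]
        centers = (edges[:-1] + edges[1:]) / 2.0
        final = out["maps"][-1]
        com_x = (final.sum(axis=0) * centers).sum() / final.sum()
        assert com_x > 0.5  # displaced toward the +x source

    def test_particle_number_conserved(self):
        cfg = SimulationConfig(substrate=self.SOURCE, n_particles=300,
                               duration_s=0.2, seed=3)
        out = dish_scenario(cfg, dish_radius_um=50.0,
                            sample_times_s=(0.0, 0.1, 0.2))
        assert np.all(out["counts"] == 300)

    def test_source_outside_dish_rejected(self):
        cfg = SimulationConfig(substrate=self.SOURCE, n_particles=10,
                               duration_s=0.01, seed=3)
        from chemoswim.errors import GeometryError
        with pytest.raises(GeometryError):
            dish_scenario(cfg, dish_radius_um=20.0)
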