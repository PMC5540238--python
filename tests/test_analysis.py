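"""MSD estimation, fits, motion classification, drift and polarization."""

import math

import numpy as np
import pandas as pd
import pytest

from chemoswim.analysis import (MSDCurve, classify_motion, compute_msd,
                                drift_velocity, estimate_diffusion,
                                fit_ballistic_msd, fit_linear_msd,
                                polarization_histogram)
from chemoswim.errors import FitError, InsufficientDataError, ParameterError
from chemoswim.physics import translational_diffusion


def make_track(xy: np.ndarray, fps: float = 30.0, track_id: int = 0) -> pd.DataFrame:
    n = len(xy)
    return pd.DataFrame({
        "track_id": track_id, "frame": np.arange(n),
        "time_s": np.arange(n) / fps,
        "x_um": xy[:, 0], "y_um": xy[:, 1],
    })


def synthetic_curve(lags, msd):
    lags = np.asarray(lags, float)
    msd = np.asarray(msd, float)
    return MSDCurve(lags, msd, np.zeros_like(msd), 1)


class TestComputeMSD:
    def test_stationary_track_zero(self):
        tracks = make_track(np.zeros((31, 2)))
        curve = compute_msd(tracks)
        assert np.allclose(curve.msd_um2, 0.0)

    def test_ballistic_identity(self):
        # straight run at speed v: MSD(tau) = v^2 tau^2 exactly
        v = 12.0
        t = np.arange(31) / 30.0
        tracks = make_track(np.column_stack([v * t, np.zeros_like(t)]))
        curve = compute_msd(tracks)
        assert np.allclose(curve.msd_um2, (v * curve.lag_times_s) ** 2, rtol=1e-10)

    def test_empty_input_rejected(self):
        with pytest.raises(InsufficientDataError):
            compute_msd(pd.DataFrame(columns=["track_id", "frame", "time_s",
                                              "x_um", "y_um"]))

    def test_gap_tolerant(self):
        v = 6.0
        t = np.arange(31) / 30.0
        df = make_track(np.column_stack([v * t, np.zeros_like(t)]))
        df = df[df["frame"] != 7]  # drop one detection
        curve = compute_msd(df)
        assert np.allclose(curve.msd_um2, (v * curve.lag_times_s) ** 2, rtol=1e-10)

    def test_passive_ensemble_recovers_diffusivity(self, passive_tracks, body_medium):
        # fitted slope / 4 must sit within 3 SE of Stokes-Einstein D_0
        D, se = estimate_diffusion(passive_tracks)
        D0 = translational_diffusion(body_medium, 50.0)
        assert abs(D - D0) < 3.0 * se


class TestLinearFit:
    def test_exact_line(self):
        lags = np.linspace(0, 1, 31)
        curve = synthetic_curve(lags, 4 * 2.5 * lags)
        D, _ = fit_linear_msd(curve)
        assert D == pytest.approx(2.5)

    def test_intercept_absorbed(self):
        lags = np.linspace(0, 1, 31)
        curve = synthetic_curve(lags, 4 * 2.5 * lags + 0.8)
        D, _ = fit_linear_msd(curve)
        assert D == pytest.approx(2.5)

    def test_window_too_small(self):
        curve = synthetic_curve([0.0, 0.1, 0.2], [0.0, 1.0, 2.0])
        with pytest.raises(FitError):
            fit_linear_msd(curve, lag_window=(0.0, 0.05))


class TestBallisticFit:
    def test_exact_quadratic(self):
        lags = np.linspace(0, 1, 31)
        curve = synthetic_curve(lags, 4 * 2.0 * lags + (10.0 * lags) ** 2)
        D, v, degenerate = fit_ballistic_msd(curve)
        assert D == pytest.approx(2.0, abs=1e-9)
        assert v == pytest.approx(10.0, abs=1e-9)
        assert not degenerate

    def test_pure_linear_gives_zero_drift(self):
        lags = np.linspace(0, 1, 31)
        curve = synthetic_curve(lags, 4 * 2.0 * lags)
        _, v, _ = fit_ballistic_msd(curve)
        assert v == pytest.approx(0.0, abs=1e-6)

    def test_negative_curvature_flagged(self):
        lags = np.linspace(0.01, 1, 31)
        msd = 4 * 2.0 * lags - 1.5 * lags**2
        curve = synthetic_curve(lags, np.maximum(msd, 1e-9))
        _, v, degenerate = fit_ballistic_msd(curve)
        assert v == 0.0
        assert degenerate

    def test_gated_ensemble_drift(self, gated_tracks):
        # ballistic MSD component of the gated ensemble approximates the
        # closed-form drift V0 * 5/42 = 20 um/s for p = 10
        curve = compute_msd(gated_tracks)
        _, v, _ = fit_ballistic_msd(curve)
        assert v == pytest.approx(20.0, rel=0.15)


class TestClassification:
    def test_exact_linear_is_fickian(self):
        lags = np.linspace(1 / 30, 1, 30)
        assert classify_motion(synthetic_curve(lags, 26.0 * lags)) == "Fickian"

    def test_exact_quadratic_is_superdiffusive(self):
        lags = np.linspace(1 / 30, 1, 30)
        assert classify_motion(synthetic_curve(lags, 400.0 * lags**2)) == \
            "superdiffusive"

    def test_intermediate_is_indeterminate(self):
        lags = np.linspace(1 / 30, 1, 30)
        assert classify_motion(synthetic_curve(lags, lags**1.18)) == "indeterminate"

    def test_nonpositive_msd_rejected(self):
        lags = np.linspace(1 / 30, 1, 30)
        msd = 26.0 * lags
        msd[5] = 0.0
        with pytest.raises(Exception):
            classify_motion(synthetic_curve(lags, msd))


class TestDrift:
    def test_mirror_symmetric_cancels(self):
        t = np.arange(31) / 30.0
        right = make_track(np.column_stack([5 * t, np.zeros_like(t)]), track_id=0)
        left = make_track(np.column_stack([-5 * t, np.zeros_like(t)]), track_id=1)
        tracks = pd.concat([right, left], ignore_index=True)
        est = drift_velocity(tracks, (1.0, 0.0), [0.0, 1.01])
        assert est[0].drift_um_s == pytest.approx(0.0, abs=1e-12)

    def test_straight_tracks_along_gradient(self):
        t = np.arange(31) / 30.0
        tracks = pd.concat([
            make_track(np.column_stack([20 * t, np.zeros_like(t)]), track_id=i)
            for i in range(3)
        ], ignore_index=True)
        est = drift_velocity(tracks, (1.0, 0.0), [0.0, 1.01])
        assert est[0].drift_um_s == pytest.approx(20.0)

    def test_non_unit_gradient_rejected(self):
        t = np.arange(5) / 30.0
        tracks = make_track(np.column_stack([t, t]))
        with pytest.raises(ParameterError):
            drift_velocity(tracks, (2.0, 0.0), [0.0, 1.0])

    def test_empty_bins_omitted(self):
        t = np.arange(31) / 30.0
        tracks = make_track(np.column_stack([t, t]))
        est = drift_velocity(tracks, (1.0, 0.0), [0.0, 1.01, 5.0, 6.0])
        assert len(est) == 1

    def test_gated_ensemble_drifts_up_gradient(self, gated_tracks):
        est = drift_velocity(gated_tracks, (1.0, 0.0), [0.0, 1.01])
        assert est[0].drift_um_s > 3.0 * est[0].se_um_s


class TestPolarization:
    def test_percent_sums_to_100(self, passive_tracks):
        hist = polarization_histogram(passive_tracks, (1.0, 0.0), n_bins=18)
        assert hist.percent.sum() == pytest.approx(100.0)

    def test_isotropic_walks_near_uniform(self, passive_tracks):
        n_bins = 8
        hist = polarization_histogram(passive_tracks, (1.0, 0.0), n_bins=n_bins)
        n_tracks = passive_tracks["track_id"].nunique()
        # binomial SE per bin, in percent
        p = 1.0 / n_bins
        se = 100.0 * math.sqrt(p * (1 - p) / n_tracks)
        assert np.all(np.abs(hist.percent - 100.0 / n_bins) < 4.0 * se)

    def test_aligned_tracks_in_zero_bin(self):
        t = np.arange(31) / 30.0
        tracks = pd.concat([
            make_track(np.column_stack([7 * t, 0.01 * t]), track_id=i)
            for i in range(5)
        ], ignore_index=True)
        hist = polarization_histogram(tracks, (1.0, 0.0), n_bins=18)
        zero_bin = np.searchsorted(hist.bin_edges_deg, 0.0, side="right") - 1
        assert hist.percent[zero_bin] == pytest.approx(100.0)

    def test_gated_ensemble_mode_at_zero(self, gated_tracks):
        # the modal bin hugs 0 deg (either side: the distribution is
        # symmetric about the gradient axis)
        hist = polarization_histogram(gated_tracks, (1.0, 0.0), n_bins=18)
        mode = hist.percent.argmax()
        centre = (hist.bin_edges_deg[mode] + hist.bin_edges_deg[mode + 1]) / 2
        assert abs(centre) < 20.0
        # and the two bins flanking 0 deg hold the majority of tracks
        flank = np.searchsorted(hist.bin_edges_deg, 0.0, side="right") - 1
        assert hist.percent[flank - 1] + hist.percent[flank] > 50.0

    def test_zero_displacement_excluded(self):
        still = make_track(np.zeros((31, 2)), track_id=0)
        t = np.arange(31) / 30.0
        moving = make_track(np.column_stack([t, t]), track_id=1)
        hist = polarization_histogram(pd.concat([still, moving],
                                                ignore_index=True), (1.0, 0.0))
        assert hist.n_excluded == 1

    def test_odd_bin_count_rejected(self):
        t = np.arange(5) / 30.0
        with pytest.raises(ParameterError):
            polarization_histogram(make_track(np.column_stack([t, t])),
                                   (1.0, 0.0), n_bins=7)
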