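"""Trajectory statistics for nanoparticle-tracking data.

Implements the standard single-particle-tracking pipeline applied to
NTA track tables: time-averaged mean-square displacement with
overlapping windows, diffusive and ballistic MSD fits, motion-class
diagnostics (Fickian vs. superdiffusive), drift velocity along a
chemical gradient, polarization histograms of track directions, and
inference of the propulsion speed by fitting simulated ensembles to an
observed MSD curve.

A track table is a pandas DataFrame with columns
``track_id, frame, time_s, x_um, y_um`` at a fixed frame rate; frames
may have gaps (dropped detections) — lag statistics then use the pairs
that exist.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .errors import DataError, FitError, InsufficientDataError, ParameterError
from .physics import Medium
from .simulate import SimulationConfig, gated_config, simulate_tracks
from .swimmer import SwimmerGeometry


@dataclass(frozen=True)
class MSDCurve:
    """Ensemble MSD: lag times (s), values (μm²), per-lag SE, track count."""

    lag_times_s: np.ndarray
    msd_um2: np.ndarray
    se_um2: np.ndarray
    n_tracks: int

    def __post_init__(self) -> None:
        if np.any(np.diff(self.lag_times_s) <= 0):
            raise DataError("lag times must be strictly increasing")
        if np.any(self.msd_um2 < 0):
            raise DataError("MSD values must be non-negative")


@dataclass(frozen=True)
class DriftEstimate:
    """Signed drift velocity along the gradient axis within one time window."""

    drift_um_s: float
    se_um_s: float
    window_s: tuple
    n_tracks: int

    def __post_init__(self) -> None:
        if not self.window_s[0] < self.window_s[1]:
            raise ParameterError("window start must precede end")


@dataclass(frozen=True)
class PolarizationHistogram:
    """Percent of tracks per angular bin over [-180, 180] degrees."""

    bin_edges_deg: np.ndarray
    percent: np.ndarray
    n_excluded: int

    def __post_init__(self) -> None:
        if abs(self.percent.sum() - 100.0) > 1e-6:
            raise DataError("percentages must sum to 100")


@dataclass(frozen=True)
class PropulsionEstimate:
    """Best-fit propulsion speed with a bootstrap min/max range."""

    best_um_s: float
    min_um_s: float
    max_um_s: float
    objective: float
    indeterminate: bool = False

    def __post_init__(self) -> None:
        if not (self.min_um_s <= self.best_um_s <= self.max_um_s):
            raise ParameterError("range must bracket the best estimate")


def _track_arrays(tracks: pd.DataFrame):
    """Yield (track_id, frames, xy) per track, sorted by frame."""
    for tid, df in tracks.groupby("track_id", sort=False):
        df = df.sort_values("frame")
        yield tid, df["frame"].to_numpy(dtype=np.int64), df[["x_um", "y_um"]].to_numpy()


def _per_track_msd(frames: np.ndarray, xy: np.ndarray, max_n: int) -> np.ndarray:
    """Time-averaged MSD with overlapping windows for one track.

    Returns an array of length max_n (lags 1..max_n in frame units) with
    NaN where a lag has no pairs.  Frame gaps are handled by spreading
    the positions onto a dense frame grid.
    """
    f0, f1 = frames[0], frames[-1]
    span = int(f1 - f0) + 1
    dense = np.full((span, 2), np.nan)
    dense[frames - f0] = xy
    out = np.full(max_n, np.nan)
    for lag in range(1, min(max_n, span - 1) + 1):
        d = dense[lag:] - dense[:-lag]
        sq = d[:, 0] ** 2 + d[:, 1] ** 2
        good = ~np.isnan(sq)
        if good.any():
            out[lag - 1] = sq[good].mean()
    return out


def _frame_interval(tracks: pd.DataFrame) -> float:
    t = tracks.sort_values(["track_id", "frame"])
    df = t["frame"].diff().to_numpy()
    dt = t["time_s"].diff().to_numpy()
    same = t["track_id"].diff().to_numpy() == 0
    good = same & (df > 0)
    if not good.any():
        raise InsufficientDataError("no consecutive frames found")
    return float(np.median(dt[good] / df[good]))


def compute_msd(tracks: pd.DataFrame, max_lag_s: float = 1.0) -> MSDCurve:
    """Ensemble MSD from a track table.

    Per-track time-averaged MSD with overlapping windows,
    ``MSD(n Δt) = mean_i |r_{i+n} - r_i|²``, then an unweighted mean over
    tracks; the SE at each lag is the across-track standard deviation
    divided by √(number of tracks contributing).  Lag 0 (MSD = 0) is
    included.
    """
    if tracks is None or len(tracks) == 0:
        raise InsufficientDataError("empty track table")
    frame_dt = _frame_interval(tracks)
    max_n = max(1, int(round(max_lag_s / frame_dt)))
    rows = []
    for tid, frames, xy in _track_arrays(tracks):
        if frames.size < 2:
            continue
        rows.append(_per_track_msd(frames, xy, max_n))
    if not rows:
        raise InsufficientDataError("no track has at least 2 frames")
    M = np.vstack(rows)
    counts = (~np.isnan(M)).sum(axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.where(counts > 0, np.nanmean(M, axis=0), np.nan)
        sd = np.where(counts > 1, np.nanstd(M, axis=0, ddof=1), np.nan)
    se = sd / np.sqrt(np.maximum(counts, 1))
    keep = counts > 0
    lags = np.arange(1, max_n + 1)[keep] * frame_dt
    return MSDCurve(
        lag_times_s=np.concatenate([[0.0], lags]),
        msd_um2=np.concatenate([[0.0], mean[keep]]),
        se_um2=np.concatenate([[0.0], se[keep]]),
        n_tracks=M.shape[0],
    )


def _fit_window(curve: MSDCurve, lag_window) -> np.ndarray:
    lags = curve.lag_times_s
    if lag_window is None:
        # bias/variance compromise: short-lag third of the curve
        lag_window = (0.0, lags.max() / 3.0)
    lo, hi = lag_window
    mask = (lags > max(lo, 0.0)) & (lags <= hi * (1 + 1e-9))
    return mask


def fit_linear_msd(curve: MSDCurve, lag_window=None) -> tuple[float, float]:
    """Diffusion coefficient from the linear MSD regime (2D convention).

    Ordinary least squares of MSD = 4 D τ + b with a free intercept (the
    intercept absorbs the static localization-noise offset).  Returns
    (D, SE_D) in μm²/s.
    """
    mask = _fit_window(curve, lag_window)
    if mask.sum() < 3:
        raise FitError("need at least 3 lags inside the fit window")
    x = curve.lag_times_s[mask]
    ydat = curve.msd_um2[mask]
    A = np.column_stack([x, np.ones_like(x)])
    coef, res, *_ = np.linalg.lstsq(A, ydat, rcond=None)
    slope = coef[0]
    dof = x.size - 2
    if dof > 0:
        resid = ydat - A @ coef
        s2 = float(resid @ resid) / dof
        cov = s2 * np.linalg.inv(A.T @ A)
        se_slope = math.sqrt(cov[0, 0])
    else:
        se_slope = float("nan")
    return slope / 4.0, se_slope / 4.0


def estimate_diffusion(tracks: pd.DataFrame, n_groups: int = 10,
                       lag_window=None, max_lag_s: float = 1.0
                       ) -> tuple[float, float]:
    """Ensemble diffusion coefficient with an honest standard error.

    MSD values at different lags of the same track ensemble are strongly
    correlated, so the residual-based SE of a single straight-line fit is
    optimistic.  Here the tracks are split into ``n_groups`` interleaved
    groups, the slope is fitted per group, and the estimate is the group
    mean with the SE of the mean — uncertainty measured across
    independent subsets of particles.
    """
    ids = tracks["track_id"].unique()
    if ids.size < n_groups:
        raise InsufficientDataError("fewer tracks than groups")
    ds = []
    for k in range(n_groups):
        sub = tracks[tracks["track_id"].isin(ids[k::n_groups])]
        D, _ = fit_linear_msd(compute_msd(sub, max_lag_s=max_lag_s), lag_window)
        ds.append(D)
    ds = np.asarray(ds)
    return float(ds.mean()), float(ds.std(ddof=1) / math.sqrt(n_groups))


def fit_ballistic_msd(curve: MSDCurve, lag_window=None) -> tuple[float, float, bool]:
    """Diffusion + drift from MSD(τ) = 4 D τ + (v_d τ)².

    Non-negative least squares on the (τ, τ²) design; returns
    ``(D, v_d, degenerate)`` where ``degenerate`` flags a
    negative-curvature fit clipped to v_d = 0.
    """
    lags = curve.lag_times_s
    mask = lags > 0 if lag_window is None else _fit_window(curve, lag_window)
    if mask.sum() < 4:
        raise FitError("need at least 4 lags for the ballistic fit")
    x = lags[mask]
    ydat = curve.msd_um2[mask]
    A = np.column_stack([x, x**2])
    # detect negative curvature with an unconstrained fit first
    free, *_ = np.linalg.lstsq(A, ydat, rcond=None)
    coef, _ = nnls(A, ydat)
    degenerate = free[1] < 0
    return coef[0] / 4.0, math.sqrt(coef[1]), degenerate


def classify_motion(curve: MSDCurve, fickian_band=(0.9, 1.1),
                    superdiffusive_min: float = 1.25) -> str:
    """Log-log MSD slope diagnostic: Fickian / superdiffusive / indeterminate.

    The slope of log MSD vs log τ over the positive lags is ~1 for free
    diffusion and ~2 for directed motion; thresholds are chosen so that
    passive statistical noise rarely leaves the Fickian band.
    """
    mask = curve.lag_times_s > 0
    if mask.sum() < 5:
        raise FitError("need at least 5 positive lags to classify")
    y = curve.msd_um2[mask]
    if np.any(y <= 0):
        raise DataError("MSD values must be positive to classify on a log scale")
    s = np.polyfit(np.log(curve.lag_times_s[mask]), np.log(y), 1)[0]
    if fickian_band[0] <= s <= fickian_band[1]:
        return "Fickian"
    if s >= superdiffusive_min:
        return "superdiffusive"
    return "indeterminate"


def drift_velocity(tracks: pd.DataFrame, gradient_direction,
                   time_bins) -> list[DriftEstimate]:
    """Mean drift along the gradient axis per time bin.

    For each bin and each track with ≥2 frames inside it, the signed
    projection of the net displacement onto the gradient unit vector is
    divided by the elapsed time; the estimate is the across-track mean
    with its standard error.  Empty bins are omitted.
    """
    g = np.asarray(gradient_direction, dtype=float)[:2]
    norm = np.linalg.norm(g)
    if not math.isclose(norm, 1.0, rel_tol=1e-6):
        raise ParameterError("gradient_direction must be a unit 2D vector")
    g = g / norm
    edges = np.asarray(time_bins, dtype=float)
    out = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        vals = []
        for tid, df in tracks.groupby("track_id", sort=False):
            sel = df[(df["time_s"] >= lo) & (df["time_s"] < hi)].sort_values("frame")
            if len(sel) < 2:
                continue
            dt = sel["time_s"].iloc[-1] - sel["time_s"].iloc[0]
            if dt <= 0:
                continue
            disp = sel[["x_um", "y_um"]].iloc[-1].to_numpy() - \
                sel[["x_um", "y_um"]].iloc[0].to_numpy()
            vals.append(float(disp @ g) / dt)
        if vals:
            v = np.asarray(vals)
            se = v.std(ddof=1) / math.sqrt(v.size) if v.size > 1 else float("nan")
            out.append(DriftEstimate(float(v.mean()), float(se), (lo, hi), v.size))
    return out


def polarization_histogram(tracks: pd.DataFrame, gradient_direction,
                           n_bins: int = 18) -> PolarizationHistogram:
    """Distribution of track directions relative to the gradient.

    The angle of each track's net displacement with respect to the
    gradient direction is binned over [-180°, 180°]; perfect alignment
    with the gradient sits at 0°.  Zero-displacement tracks are excluded
    and counted.
    """
    if n_bins < 4 or n_bins % 2:
        raise ParameterError("n_bins must be an even number >= 4")
    g = np.asarray(gradient_direction, dtype=float)[:2]
    g = g / np.linalg.norm(g)
    angles = []
    excluded = 0
    for tid, frames, xy in _track_arrays(tracks):
        disp = xy[-1] - xy[0]
        if np.hypot(*disp) == 0.0:
            excluded += 1
            continue
        along = disp @ g
        perp = disp[0] * (-g[1]) + disp[1] * g[0]
        angles.append(math.degrees(math.atan2(perp, along)))
    if not angles:
        raise InsufficientDataError("no track has a non-zero net displacement")
    edges = np.linspace(-180.0, 180.0, n_bins + 1)
    counts, _ = np.histogram(angles, bins=edges)
    percent = counts / counts.sum() * 100.0
    return PolarizationHistogram(edges, percent, excluded)


def _objective(sim: np.ndarray, obs: np.ndarray) -> float:
    """Mean squared relative deviation between two MSD curves."""
    good = obs > 0
    return float(np.mean(((sim[good] - obs[good]) / obs[good]) ** 2))


def simulate_candidate_curves(candidate_grid, geometry: SwimmerGeometry,
                              medium: Medium, n_sim: int, seed: int,
                              fps: float = 30.0, duration_s: float = 1.0,
                              max_lag_s: float = 1.0) -> dict[float, MSDCurve]:
    """MSD curves of gated-propulsion ensembles for each candidate speed.

    Each candidate V0 is simulated under the acquisition protocol
    (default 30 fps, 1 s) in a saturated uniform gradient with the
    geometric gating exponent.
    """
    curves = {}
    for k, v0 in enumerate(candidate_grid):
        cfg = gated_config(float(v0), geometry=geometry, medium=medium,
                           n_particles=n_sim, duration_s=duration_s,
                           seed=seed + 7919 * k)
        sim_tracks = simulate_tracks(cfg, fps=fps)
        curves[float(v0)] = compute_msd(sim_tracks, max_lag_s=max_lag_s)
    return curves


def infer_propulsion(tracks: pd.DataFrame, geometry: SwimmerGeometry,
                     medium: Medium, candidate_grid, n_sim: int = 300,
                     seed: int = 0, fps: float = 30.0, duration_s: float = 1.0,
                     n_bootstrap: int = 200,
                     candidate_curves: dict[float, MSDCurve] | None = None,
                     ) -> PropulsionEstimate:
    """Propulsion-speed inference by simulation fitting.

    For each candidate V0 an ensemble of gated swimmers is simulated
    under the acquisition protocol and its MSD compared with the
    observed curve through the mean squared relative deviation; the best
    V0 minimises the objective.  The min/max range comes from refitting
    200 bootstrap resamples of the observed tracks against the same
    candidate curves.  A pre-simulated candidate library can be supplied
    to amortise the simulation cost across datasets.
    """
    grid = [float(v) for v in candidate_grid]
    if len(grid) < 2:
        raise ParameterError("candidate grid must contain at least 2 speeds")
    observed = compute_msd(tracks, max_lag_s=duration_s)
    if candidate_curves is None:
        candidate_curves = simulate_candidate_curves(
            grid, geometry, medium, n_sim, seed, fps, duration_s,
            max_lag_s=duration_s)
    # align candidate curves on the observed lag grid
    obs_lags = observed.lag_times_s
    sims = {}
    for v0, c in candidate_curves.items():
        if c.lag_times_s.size < obs_lags.size:
            raise FitError("candidate curve has fewer lags than the observed one")
        sims[v0] = np.interp(obs_lags, c.lag_times_s, c.msd_um2)

    objs = {v0: _objective(sims[v0], observed.msd_um2) for v0 in grid}
    best = min(objs, key=objs.get)
    spread = max(objs.values()) - min(objs.values())
    indeterminate = spread < 1e-3

    # bootstrap over tracks: recompute the ensemble curve from the cached
    # per-track MSD matrix, then refit against the same candidate curves
    frame_dt = _frame_interval(tracks)
    max_n = obs_lags.size - 1
    per_track = np.vstack([
        _per_track_msd(frames, xy, max_n)
        for tid, frames, xy in _track_arrays(tracks)
    ])
    rng = np.random.default_rng(seed + 1)
    n_tracks = per_track.shape[0]
    boot_best = []
    for _ in range(n_bootstrap):
        idx = rng.integers(0, n_tracks, n_tracks)
        m = np.nanmean(per_track[idx], axis=0)
        boot_obs = np.concatenate([[0.0], m])
        b = min(grid, key=lambda v0: _objective(sims[v0], boot_obs))
        boot_best.append(b)
    lo = min(boot_best + [best])
    hi = max(boot_best + [best])
    return PropulsionEstimate(best, lo, hi, objs[best], indeterminate)
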