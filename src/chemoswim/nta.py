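"""Synthetic nanoparticle-tracking-analysis (NTA) data generation and I/O.

NTA instruments record dark-field videos of thousands of nanoparticles
and link detections into 2D tracks at a fixed frame rate.  This module
emulates that acquisition on top of the stochastic swimmer simulator:
camera sampling of the 2D projection, isotropic Gaussian localization
noise, independent per-frame detection dropout that fragments tracks,
and the minimum-duration filter applied before analysis.  The reference
protocol is 30 fps recordings of up to 60 s with a 1-s minimum track
duration and thousands of tracks per sample.

Ground truth (the propulsion speed, diffusivities and seeds behind a
dataset) is returned alongside — and written as a JSON sidecar by the
CLI — so parameter-recovery tests never have to peek through the
analysis path.
"""

from __future__ import annotations

import io
import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .errors import DataError, InsufficientDataError, ParameterError
from .simulate import (SimulationConfig, TRACK_COLUMNS, project_to_tracks,
                       simulate_ensemble)

#: Typical NTA localization precision, nm.
DEFAULT_LOCALIZATION_SIGMA_NM = 20.0


@dataclass(frozen=True)
class NTAScenario:
    """Acquisition settings layered on top of a simulation config."""

    config: SimulationConfig
    fps: float = 30.0
    recording_s: float = 1.0
    localization_sigma_nm: float = DEFAULT_LOCALIZATION_SIGMA_NM
    dropout_per_frame: float = 0.0
    min_duration_s: float = 1.0

    def __post_init__(self) -> None:
        if not (self.fps > 0):
            raise ParameterError("fps must be positive")
        if self.min_duration_s < 1.0 / self.fps:
            raise ParameterError("minimum duration must cover at least one frame interval")
        if self.localization_sigma_nm < 0:
            raise ParameterError("localization sigma must be non-negative")
        if not (0.0 <= self.dropout_per_frame < 1.0):
            raise ParameterError("dropout probability must lie in [0, 1)")
        if self.recording_s > self.config.duration_s + 1e-12:
            raise ParameterError("recording cannot outlast the simulated duration")


def _fragment(keep: np.ndarray, min_frames: int):
    """Split a track at dropped frames; yield surviving (start, stop) runs."""
    runs = []
    start = None
    for i, k in enumerate(keep):
        if k and start is None:
            start = i
        elif not k and start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, keep.size))
    for a, b in runs:
        if b - a >= min_frames:
            yield a, b


def generate_nta_dataset(scenario: NTAScenario, seed: int | None = None
                         ) -> tuple[pd.DataFrame, dict]:
    """Simulate an acquisition and return (track table, ground truth).

    The underlying 3D ensemble is projected to the camera plane at the
    scenario frame rate; localization noise is added per detection, each
    detection is independently dropped with the per-frame probability,
    tracks are split at dropped frames, and fragments shorter than the
    minimum duration are discarded (fragments keep their frame/time
    stamps but get fresh track ids).
    """
    cfg = scenario.config
    if seed is not None:
        from dataclasses import replace
        cfg = replace(cfg, seed=seed)
    stride = (1.0 / scenario.fps) / cfg.dt_s
    if abs(stride - round(stride)) > 1e-6:
        raise ParameterError("1/fps must be a multiple of the integration step")
    result = simulate_ensemble(cfg, record_stride=int(round(stride)))
    table = project_to_tracks(result, scenario.fps, scenario.recording_s)

    ss = np.random.SeedSequence([cfg.seed, 2**16 + 1])
    noise_rng = np.random.default_rng(ss)
    sigma_um = scenario.localization_sigma_nm * 1e-3
    if sigma_um > 0:
        table = table.copy()
        table[["x_um", "y_um"]] += noise_rng.normal(0.0, sigma_um, (len(table), 2))

    min_frames = int(round(scenario.min_duration_s * scenario.fps)) + 1
    frames_per_track = int(round(scenario.recording_s * scenario.fps)) + 1
    pieces = []
    next_id = 0
    for tid, df in table.groupby("track_id", sort=True):
        if scenario.dropout_per_frame > 0:
            keep = noise_rng.random(len(df)) >= scenario.dropout_per_frame
        else:
            keep = np.ones(len(df), dtype=bool)
        df = df.sort_values("frame").reset_index(drop=True)
        for a, b in _fragment(keep, min_frames):
            frag = df.iloc[a:b].copy()
            frag["track_id"] = next_id
            next_id += 1
            pieces.append(frag)
    if not pieces:
        raise InsufficientDataError(
            f"all tracks were filtered out (dropout={scenario.dropout_per_frame}, "
            f"min duration={scenario.min_duration_s}s over {frames_per_track} frames)"
        )
    out = pd.concat(pieces, ignore_index=True)

    d = cfg.diffusion()
    truth = {
        "V0_um_s": cfg.law.V0_um_s,
        "exponent": cfg.law.exponent,
        "gated": cfg.gated,
        "D_t_um2_s": d.D_t_um2_s,
        "D_r_rad2_s": d.D_r_rad2_s,
        "seed": cfg.seed,
        "fps": scenario.fps,
        "recording_s": scenario.recording_s,
        "localization_sigma_nm": scenario.localization_sigma_nm,
        "dropout_per_frame": scenario.dropout_per_frame,
        "min_duration_s": scenario.min_duration_s,
        "n_tracks_simulated": cfg.n_particles,
        "n_tracks_surviving": int(out["track_id"].nunique()),
    }
    return out, truth


def write_tracks(table: pd.DataFrame, path) -> None:
    """Write a track table as comma-delimited text with header."""
    missing = [c for c in TRACK_COLUMNS if c not in table.columns]
    if missing:
        raise DataError(f"track table lacks columns: {missing}")
    table[TRACK_COLUMNS].to_csv(path, index=False)


def read_tracks(path) -> pd.DataFrame:
    """Read and validate a track table.

    Rows are canonically sorted by (track_id, frame).  Malformed rows
    are rejected with their 1-based file line numbers; frame gaps within
    a track are accepted.  Non-monotone (duplicate) frames within a
    track raise a :class:`DataError`.
    """
    raw = pd.read_csv(path, dtype=str, skip_blank_lines=False)
    missing = [c for c in TRACK_COLUMNS if c not in raw.columns]
    if missing:
        raise DataError(f"missing required columns: {missing}")
    numeric = {}
    bad_lines: list[int] = []
    for col in TRACK_COLUMNS:
        converted = pd.to_numeric(raw[col], errors="coerce")
        bad_lines.extend((raw.index[converted.isna()] + 2).tolist())  # header + 1-based
        numeric[col] = converted
    if bad_lines:
        raise DataError(f"malformed rows at lines {sorted(set(bad_lines))}")
    table = pd.DataFrame(numeric)
    table["track_id"] = table["track_id"].astype(np.int64)
    table["frame"] = table["frame"].astype(np.int64)
    table = table.sort_values(["track_id", "frame"]).reset_index(drop=True)
    dup = table.duplicated(subset=["track_id", "frame"])
    if dup.any():
        raise DataError("non-monotone frames: duplicate (track_id, frame) pairs")
    return table


def frame_gaps(table: pd.DataFrame) -> dict[int, list[int]]:
    """Missing frame indices per track (linking gaps in the acquisition)."""
    gaps = {}
    for tid, df in table.groupby("track_id"):
        f = df["frame"].sort_values().to_numpy()
        missing = sorted(set(range(int(f[0]), int(f[-1]) + 1)) - set(f.tolist()))
        if missing:
            gaps[int(tid)] = missing
    return gaps


def write_ground_truth(truth: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
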