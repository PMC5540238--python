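"""Passive vs chemotactic ensembles through the tracking-analysis pipeline.

Simulates a passive control and a gated chemotactic ensemble (uniform
glucose gradient along +x), samples both like an NTA camera (30 fps,
1 s), and runs the full trajectory-statistics pipeline: MSD + motion
class, drift velocity along the gradient, and the polarization
histogram.
"""

import numpy as np

from chemoswim.analysis import (classify_motion, compute_msd, drift_velocity,
                                fit_ballistic_msd, polarization_histogram)
from chemoswim.simulate import SimulationConfig, gated_config, simulate_tracks

passive_cfg = SimulationConfig(n_particles=500, duration_s=1.0, seed=1)
gated_cfg = gated_config(168.0, n_particles=500, duration_s=1.0, seed=2)

for name, cfg in [("passive", passive_cfg), ("chemotactic", gated_cfg)]:
    tracks = simulate_tracks(cfg, fps=30.0)
    curve = compute_msd(tracks)
    label = classify_motion(curve)
    D, v_d, _ = fit_ballistic_msd(curve)
    drift = drift_velocity(tracks, (1.0, 0.0), [0.0, 1.01])[0]
    hist = polarization_histogram(tracks, (1.0, 0.0), n_bins=18)
    mode = hist.percent.argmax()
    centre = (hist.bin_edges_deg[mode] + hist.bin_edges_deg[mode + 1]) / 2
    print(f"--- {name} ---")
    print(f"  motion class     : {label}   (log-log MSD slope diagnostic)")
    print(f"  ballistic fit    : D = {D:.2f} um^2/s, drift speed = {v_d:.1f} um/s")
    print(f"  drift along grad : {drift.drift_um_s:+.2f} +- {drift.se_um_s:.2f} um/s")
    print(f"  polarization mode: {centre:+.0f} deg bin "
          f"({hist.percent[mode]:.0f}% of tracks)")

print("\nA V0 = 168 um/s gated swimmer drifts at ~V0*5/42 = 20 um/s toward the"
      "\ngradient and its tracks polarize around 0 deg; the passive control is"
      "\nFickian with zero drift and a flat histogram.")
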