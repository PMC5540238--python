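# Gated chemotactic ensemble in a saturated uniform glucose gradient.
# Usable with:  chemoswim synth --config examples/configs/chemotaxis.yaml --out run/
medium:
  temperature_K: 310.15
  viscosity_mPas: 0.69
geometry:
  R_nm: 50.0
  r_patch_nm: 15.0
law:
  V0_um_s: 168.0        # propulsion cap; saturated here, so the local speed
  exponent: 10          # orientation-gating exponent nint(2*pi/alpha)
substrate:
  kind: linear
  C0: 1.0
  direction: [1.0, 0.0, 0.0]
  gradient_M_per_um: 1.0
flow:
  kind: none
chemotactic_mobility: 168.0   # chi * |grad C| >= cap -> V0_local = 168 um/s
n_particles: 500
dt_s: 3.3333333333333335e-05
duration_s: 1.0
seed: 42
acquisition:
  fps: 30.0
  recording_s: 1.0
  localization_sigma_nm: 20.0
  dropout_per_frame: 0.0
  min_duration_s: 1.0
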