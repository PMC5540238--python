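"""Diffusion scales of a 50 nm vesicle in water at body temperature.

Prints the Stokes-Einstein translational and rotational diffusion
coefficients, the orientation randomisation time, the effective
diffusion of a self-propelled sphere, and Péclet numbers for the two
flow speeds used in the flow-chamber experiments.
"""

from chemoswim.physics import (Medium, diffusion_set, effective_diffusion,
                               peclet)

medium = Medium(temperature_K=310.15, viscosity_mPas=0.69)
d = diffusion_set(medium, radius_nm=50.0)

print(f"D_t  = {d.D_t_um2_s:.3f} um^2/s   (passive translational diffusion)")
print(f"D_r  = {d.D_r_rad2_s:.0f} rad^2/s  (rotational diffusion)")
print(f"tau  = {d.tau_r_s * 1e3:.2f} ms      (orientation memory; propulsion "
      "direction is forgotten this fast)")

for v in (100.0, 200.0, 300.0):
    ratio = effective_diffusion(d.D_t_um2_s, d.D_r_rad2_s, v) / d.D_t_um2_s
    print(f"v = {v:3.0f} um/s -> D_eff/D_0 = {ratio:.2f}  "
          "(closed-form long-time enhancement)")

for v in (10.0, 150.0):
    print(f"flow {v:5.1f} um/s -> Pe = {peclet(v, 50.0, d.D_t_um2_s):.2f}  "
          "(advection vs diffusion over one diameter)")
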