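"""Orientation gating of propulsion by the permeable patch.

Builds the reference swimmer (R = 50 nm vesicle, r = 15 nm patch),
computes the numerical product distribution around the patch, fits the
analytic gating law A cos(beta/2)^p to it, and compares the fitted
exponent with the geometric prediction nint(2 pi / alpha).
"""

import numpy as np

from chemoswim.swimmer import (SwimmerGeometry, fit_patch_exponent,
                               product_distribution_numeric)

geom = SwimmerGeometry(R_nm=50.0, r_patch_nm=15.0)
print(f"patch sector angle alpha = {geom.alpha_rad:.4f} rad")
print(f"geometric gating exponent nint(2 pi / alpha) = {geom.exponent}")

beta, profile = product_distribution_numeric(geom, n_sources=2000)
A, p_hat, p_int = fit_patch_exponent(beta, profile)
print(f"numerical cap-source profile: fitted p = {p_hat:.2f} -> nint = {p_int}")
print("the fitted exponent matches the geometric one: the product cloud is"
      if p_int == geom.exponent else "MISMATCH:",
      "well described by V(beta) = V0 cos(beta/2)^p")

# export the profile as two-column text
np.savetxt("product_profile.txt", np.column_stack([beta, profile]),
           header="beta_rad concentration_normalized")
print("wrote product_profile.txt")
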