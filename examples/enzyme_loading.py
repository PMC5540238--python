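"""Vesicle count and enzymes-per-vesicle from shell arithmetic.

Uses a two-bin size distribution with illustrative molecular parameters
(brush length, membrane thickness, chain volume are preparation-specific
inputs) to compute aggregation numbers, the vesicle count, and the
encapsulation efficiency.
"""

from chemoswim.loading import (LoadingInputs, encapsulation_efficiency,
                               loading_report, polymersome_count)

inputs = LoadingInputs(
    size_distribution=((50.0, 0.7), (80.0, 0.3)),
    l_b_nm=5.0,            # hydrophilic brush length
    t_m_nm=6.4,            # hydrophobic membrane thickness
    v_chain_nm3=20.0,      # molecular volume of one hydrophobic chain
    copolymer_mol=1e-9,    # copolymer amount [P]
    n_enzymes=2e12,        # total enzymes in the sample
)

print(loading_report(inputs).to_string(index=False))
n_ps = polymersome_count(inputs)
e = encapsulation_efficiency(inputs.n_enzymes, n_ps)
print(f"\nN_ps = {n_ps:.3g} vesicles in the sample")
print(f"e    = {e:.2f} enzymes per vesicle on average")
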