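"""Stationary size of a single post-synaptic scaffold domain.

A condensed gephyrin domain is fed by laterally diffusing gephyrin-GlyR
complexes and drained by turnover into the cytoplasm.  With literature
estimates for the diffusion constant, turnover rate and membrane
concentration, the flux balance predicts the domain size directly.
"""

import aggscaff as ag

params = ag.PhysicalParams(
    D0=0.02,          # um^2/s, diffusion of a gephyrin-receptor complex
    k=1.0 / 1800.0,   # 1/s, turnover: residence time ~30 min
    c0=4.0 / 3.0,     # um^-2, membrane concentration of gephyrin trimers
    rho=5000.0 / 3.0,  # um^-2, trimer packing density inside a domain
)
sol = ag.domain_size(params)

print(f"depletion length  lambda = {sol.lam:.1f} um")
print(f"domain radius     R      = {sol.R * 1000:.0f} nm")
print(f"domain size       N      = {sol.N:.1f} trimers "
      f"({3 * sol.N:.0f} gephyrin monomers)")
# N ~ 70 trimers matches measured synaptic gephyrin domain sizes: diffusion,
# aggregation and turnover alone set a realistic synaptic domain size.

print("\nDomain size rises with membrane concentration:")
print(ag.sweep_domain_size(params, "c0", [0.5, 1.0, 4.0 / 3.0, 2.0, 4.0])
      .to_string(index=False))
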