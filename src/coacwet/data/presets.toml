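# Optimized generic-model couplings for the membrane-composition analogues.
#
# eps_pl : polymer-head (A-H, B-H) Lennard-Jones well depth
# omega_tt: tail-tail attraction range of the three-bead lipid model
#
# provenance:
#   published  -- value stated in the source text (5% DOPS system)
#   estimated  -- chosen by this package: the optimized pairs for the other
#                 compositions were published only as figure annotations that
#                 are not machine-readable here; these values follow the
#                 published trend (wetting strength increasing with anionic
#                 lipid content) anchored at the published 5% DOPS pair.
#   construction -- not a membrane system (droplet-only runs)

[dopc]
eps_pl = 0.700
omega_tt = 1.72
provenance = "estimated"

[dops5]
eps_pl = 0.7625
omega_tt = 1.70
provenance = "published"

[dops10]
eps_pl = 0.850
omega_tt = 1.66
provenance = "estimated"

[dops20]
eps_pl = 0.950
omega_tt = 1.60
provenance = "estimated"

[droplet-only]
eps_pl = 0.0
omega_tt = 1.70
provenance = "construction"
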