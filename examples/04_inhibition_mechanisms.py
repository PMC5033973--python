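"""Competitive vs uncompetitive vs mixed inhibition of a controlling step.

Scans the inhibition constants of the hexose phosphate isomerase (HPI)
in the hypoglycemic HeLa model under the three reversible-inhibition
mechanisms.  The scale multiplies all three physiological Ki values
(Ery4P, Fru1,6BP, 6PG) jointly; scale 1 is the experimental reference.
For each point the steady state, pathway flux, Glc6P level and the HPI
flux-control coefficient are reported.
"""

from glycontrol import preset_model
from glycontrol.experiments import ki_scan

model = preset_model("HeLa_hypo")
grid = [0.01, 0.1, 0.3, 1.0, 3.0, 10.0]

for mechanism in ("competitive", "uncompetitive", "mixed"):
    res = ki_scan(model, mechanism, ki_scale_grid=grid)
    df = res.data[["ki_scale", "pathway_flux", "Glc6P", "C_J_HPI"]]
    print(f"\n=== {mechanism} "
          f"{'(alpha = 2)' if mechanism == 'mixed' else ''} ===")
    print(df.to_string(index=False,
                       float_format=lambda x: f"{x:8.3f}"))

# Tightening Ki (scale < 1) always raises HPI's grip on the flux and
# accumulates its substrate Glc6P, but the uncompetitive mechanism is the
# most potent at every shared Ki: substrate accumulation cannot displace
# an inhibitor that binds the substrate-bound enzyme.
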