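"""Generate a synthetic véraison-cluster study and look at its design.

Builds the default study: expression for GS/PS/RS berry classes at
mid-véraison (V) and 5 weeks post-véraison (PostV), paired by replicate
plant, plus weekly physiology for GH/GS/PS/RS over six weeks.
"""

import ripesync as rs

cfg = rs.SimConfig(seed=1, n_genes=2000)
expr = rs.simulate_expression(cfg)
phys = rs.simulate_physiology(cfg)

print(f"expression matrix: {expr.matrix.shape[0]} genes x "
      f"{expr.matrix.shape[1]} samples")
print(expr.meta.groupby(["stage", "class"]).size().unstack(), "\n")
print(f"physiology rows: {len(phys)} "
      f"({phys['class'].nunique()} classes x {phys['day'].nunique()} days "
      f"x {cfg.berries_per_class_per_week} berries)")
day0 = phys[phys["day"] == 0].groupby("class")["brix"].mean().round(2)
print("\nmean °Brix at mid-véraison by class (under-ripe classes trail RS):")
print(day0.to_string())
# RS sits at ~12.6 °Brix (the R1 reference) while GH trails by ~5 °Brix,
# the spread the cluster shows at véraison before synchronization.
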