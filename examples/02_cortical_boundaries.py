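"""Profile junctional F-actin with a 2 μm bar across every boundary.

Boundaries are classified by the genotypes of their two flanking cells;
bar totals are normalised to the control-control class.  Junctions
between two mutant cells carry roughly twice the cortical F-actin,
while mixed control-mutant junctions stay at the control level.
"""

from epimech.cortical import measure_cortical
from epimech.synth import default_config, generate_scene

scene, _ = generate_scene(default_config(), "mutant", 16, seed=1)
table, stats = measure_cortical(scene, bar_length_um=2.0)

print(table.groupby("class").total_intensity.describe()[["count", "mean"]])
print("\nclass ratios to ctrl-ctrl:")
for cls, ratio in sorted(stats.ratio_to_ctrl_ctrl.items()):
    print(f"  {cls}: {ratio:.2f}")
print("\nA mut-mut ratio near 2 reproduces the two-fold cortical F-actin "
      "increase at junctions between integrin-null cells.")
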