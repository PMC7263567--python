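"""Cell morphometry: basal growth, whip counts and contraction anisotropy.

Builds the stage-resolved morphometry table, computes stage-to-stage
growth of the basal surface per genotype, counts whip-like protrusions
at leading-edge tricellular junctions, and measures the D-V/A-P
contraction anisotropy of oscillating cells.
"""

import numpy as np

from epimech.morphometry import count_whips, dv_ap_anisotropy, growth_ratios
from epimech.synth import (default_config, generate_scene,
                           simulate_morphometry, simulate_traces)

config = default_config()
table = simulate_morphometry(config, 30, seed=1)
folds = growth_ratios(table)
sel = folds[folds.stage_from.isin(["S8", "S9"])]
print(sel[["genotype", "stage_from", "stage_to", "fold_change"]]
      .to_string(index=False))
print("Control basal surfaces grow ~1.7x and ~1.8x across S8-S10; "
      "integrin-null cells lag at ~1.5x and ~1.3x.\n")

for preset in ("control", "mutant"):
    scene, truth = generate_scene(config, preset, 16, seed=3)
    counts = count_whips(truth.whips, scene)
    wanted = [c for c, v in counts.items()
              if scene.genotype[c] == ("mutant" if preset == "mutant"
                                       else "control")]
    mean = np.mean([counts[c] for c in wanted])
    print(f"{preset}: {mean:.1f} whip-like protrusions per cell at the "
          f"leading edge")

ratios = [dv_ap_anisotropy(simulate_traces(config, p, 3600, seed=2,
                                           noise_frac=0.05))
          for p in ("control", "mutant")]
print(f"\nD-V/A-P contraction anisotropy: control {ratios[0]:.1f}, "
      f"mutant {ratios[1]:.1f}")
print("Wild-type contractions are strongly polarised (~5x); integrin-null "
      "cells contract almost symmetrically (~1.2x).")
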