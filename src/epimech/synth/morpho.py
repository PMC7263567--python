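"""Synthetic per-cell morphometry tables across egg-chamber stages S6-S10.

Basal areas per stage are drawn around preset means whose stage-to-stage
ratios encode the reported growth: control basal surfaces grow 1.7x from
S8 to S9 and 1.8x from S9 to S10, mutants only 1.5x and 1.3x.  Nuclear
size is identical between genotypes (the reported null result).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import STAGES, SynthConfig

TABLE_COLUMNS = ["cell_id", "stage", "genotype", "basal_area_um2",
                 "apical_area_um2", "height_um", "nuclear_area_um2"]


def simulate_morphometry(config: SynthConfig, n_cells_per_group: int,
                         seed: int, noise_cv: float | None = None) -> pd.DataFrame:
    """Per-cell morphometry rows for both genotypes at every stage.

    ``noise_cv`` (default: each preset's ``morpho_cv``) is the per-cell
    coefficient of variation; 0 reproduces preset means exactly.  With
    ``n_cells_per_group = 0`` an empty, correctly-typed table is returned.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for genotype in ("control", "mutant"):
        preset = config.preset(genotype)
        missing = [s for s in STAGES if s not in preset.basal_area_by_stage]
        if missing:
            raise ValueError(
                f"preset {genotype!r} lacks stage presets: {missing}")
        cv = preset.morpho_cv if noise_cv is None else noise_cv
        for stage in STAGES:
            means = {
                "basal_area_um2": preset.basal_area_by_stage[stage],
                "apical_area_um2": preset.apical_area_um2,
                "height_um": preset.height_um,
                "nuclear_area_um2": preset.nuclear_area_um2,
            }
            for i in range(n_cells_per_group):
                row = {"cell_id": f"{genotype}_{stage}_{i}",
                       "stage": stage, "genotype": genotype}
                for key, mean in means.items():
                    if cv > 0:
                        value = rng.normal(mean, cv * mean)
                        value = max(value, 0.05 * mean)  # keep areas positive
                    else:
                        value = mean
                    row[key] = value
                rows.append(row)
    return pd.DataFrame(rows, columns=TABLE_COLUMNS)
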