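"""Reading and writing the package's on-disk formats.

Scenes are stored as a pair of TIFFs (float image, integer labels) plus
a genotype CSV; traces and tables as CSV; configurations as YAML.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import tifffile

from .ablation import AblationTrace
from .synth.scene import ImageScene


def save_scene(scene: ImageScene, out_dir, stem: str = "scene") -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(out / f"{stem}_image.tif",
                     scene.image.astype(np.float32))
    tifffile.imwrite(out / f"{stem}_labels.tif",
                     scene.labels.astype(np.uint16))
    pd.DataFrame({
        "cell_id": scene.cell_ids,
        "genotype": [scene.genotype[c] for c in scene.cell_ids],
    }).to_csv(out / f"{stem}_genotypes.csv", index=False)
    return out


def load_scene(image_path, labels_path, genotypes_path,
               calibration_um: float, channel: str = "factin",
               leading_edge: str = "west") -> ImageScene:
    image = tifffile.imread(image_path).astype(float)
    labels = tifffile.imread(labels_path).astype(np.int32)
    table = pd.read_csv(genotypes_path)
    genotype = dict(zip(table["cell_id"].astype(int), table["genotype"]))
    from .synth.scene import _tricellular_points
    scene = ImageScene(image=image, labels=labels, genotype=genotype,
                       tricellular_points=_tricellular_points(labels),
                       calibration=calibration_um, channel=channel,
                       leading_edge=leading_edge)
    return scene


def save_traces(bundle, path) -> None:
    t = bundle.myosin.times_s
    pd.DataFrame({
        "time_s": t,
        "myosin": bundle.myosin.values,
        "protrusion_pct": bundle.protrusion_pct.values,
        "basal_area": bundle.basal_area.values,
        "dv_length": bundle.dv_length.values,
        "ap_length": bundle.ap_length.values,
    }).to_csv(path, index=False)


def load_traces(path, dt_s: Optional[float] = None) -> pd.DataFrame:
    table = pd.read_csv(path)
    if dt_s is None and "time_s" in table.columns and len(table) > 1:
        dt_s = float(table["time_s"].iloc[1] - table["time_s"].iloc[0])
    table.attrs["dt_s"] = dt_s
    return table


def save_ablation_trace(trace: AblationTrace, path) -> None:
    cut = np.zeros(len(trace.times_s), dtype=int)
    cut[trace.cut_index] = 1
    pd.DataFrame({"time_s": trace.times_s,
                  "distance_um": trace.distance_um,
                  "cut": cut}).to_csv(path, index=False)


def load_ablation_trace(path) -> AblationTrace:
    table = pd.read_csv(path)
    cut_index = int(np.argmax(table["cut"].to_numpy()))
    return AblationTrace(times_s=table["time_s"].to_numpy(),
                         distance_um=table["distance_um"].to_numpy(),
                         cut_index=cut_index)
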